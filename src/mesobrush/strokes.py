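"""Stroke tools: articulated fibers and membranes from scripted paths.

A stroke path is resampled by arc length at the subunit spacing; subunits
become rigid bodies joined by hinges at coincident end circles, with
longer-range persistence springs (span k = 2..n_springs+1, rest length
k * spacing). Membranes additionally honor the closure rule (ends within one
segment length fuse into a clockwise vesicle with a triangulated interior;
open ends are pinned) and carry spacer colliders above and below.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

from . import defaults
from .geometry import Circle, Contour, GeometryError, polygon_area, triangulate
from .ingredients import Ingredient, IngredientError
from .physics import Fixture, Hinge, Spring, Rail

__all__ = ["StrokePath", "FiberChain", "MembraneChain", "StrokeError",
           "resample_path", "draw_fiber", "draw_membrane", "attach_to_membrane"]


class StrokeError(ValueError):
    pass


@dataclass(frozen=True)
class StrokePath:
    """Ordered polyline in nm plus a target-layer policy ("auto" or 0/1/2)."""

    points: np.ndarray
    layer: str | int = "auto"

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
            raise StrokeError("stroke path needs >= 2 points")
        if np.any(np.linalg.norm(np.diff(p, axis=0), axis=1) <= 0):
            raise StrokeError("stroke path has zero-length segments")
        object.__setattr__(self, "points", p)


@dataclass
class FiberChain:
    ingredient: str
    subunit_ids: list[int]
    hinges: list[Hinge]
    springs: list[Spring]
    layer_assignment: list[int]
    closed: bool = False
    wrap_springs: bool = False
    spacing: float = 1.0


@dataclass
class MembraneChain:
    ingredient: str
    segment_ids: list[int]
    hinges: list[Hinge]
    springs: list[Spring]
    closed: bool
    spacing: float
    thickness: float
    interior_triangles: list[np.ndarray] = field(default_factory=list)
    end_pins: list[int] = field(default_factory=list)
    compartment: str | None = None

    def rail_points(self, world) -> tuple[np.ndarray, bool]:
        pts = np.array([world.bodies[i].position for i in self.segment_ids])
        return pts, self.closed

    def enclosed_area(self, world) -> float:
        pts, closed = self.rail_points(world)
        if not closed:
            raise StrokeError("open membrane encloses no area")
        return abs(polygon_area(pts))


# ---------------------------------------------------------------------------

def resample_path(points: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length resampling; returns (samples, unit tangents)."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = int(np.floor(total / spacing + 1e-9)) + 1
    s = np.arange(n) * spacing
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    samples = np.column_stack([x, y])
    tangents = np.gradient(samples, axis=0)
    norms = np.linalg.norm(tangents, axis=1)
    tangents = tangents / np.maximum(norms, 1e-12)[:, None]
    return samples, tangents


def _is_closed(points: np.ndarray, spacing: float) -> bool:
    return float(np.linalg.norm(points[0] - points[-1])) < spacing


def _chain_constraints(ids: list[int], positions: np.ndarray, spacing: float,
                       n_springs: int, closed: bool,
                       stiffness: float = defaults.SPRING_STIFFNESS):
    """Hinge + persistence-spring topology for an ordered subunit chain."""
    n = len(ids)
    half = spacing / 2
    hinges = []
    n_h = n if closed else n - 1
    for i in range(n_h):
        j = (i + 1) % n
        hinges.append(Hinge(body_a=ids[i], body_b=ids[j],
                            anchor_a=np.array([half, 0.0]),
                            anchor_b=np.array([-half, 0.0])))
    springs = []
    for i in range(n):
        for k in range(2, n_springs + 2):
            j = i + k
            if closed:
                if k >= n:
                    continue
                j %= n
                if j < i and not closed:
                    continue
            elif j >= n:
                continue
            springs.append(Spring(body_a=ids[i], body_b=ids[j],
                                  rest_length=spacing * k, stiffness=stiffness))
    if closed:
        # deduplicate wrap spans that appear twice on short rings
        seen = set()
        uniq = []
        for s in springs:
            key = tuple(sorted((s.body_a, s.body_b))) + (round(s.rest_length, 9),)
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        springs = uniq
    return hinges, springs


def _crossing_point(path_pts: np.ndarray, chain: MembraneChain, world):
    line = LineString(path_pts)
    pts, closed = chain.rail_points(world)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    membrane = LineString(pts)
    if line.intersects(membrane):
        inter = line.intersection(membrane)
        p = inter.representative_point()
        return np.array([p.x, p.y])
    return None


def draw_fiber(scene, ingredient_name: str, path: StrokePath) -> FiberChain:
    """Instantiate an articulated fiber chain along a stroke path."""
    ing = scene.palette[ingredient_name]
    if ing.kind != "fiber":
        raise StrokeError(f"{ingredient_name!r} is not a fiber ingredient")
    spec = ing.fiber
    for chain in scene.membrane_chains:
        hit = _crossing_point(path.points, chain, scene.world)
        if hit is not None:
            raise StrokeError(
                f"fiber stroke crosses a membrane at ({hit[0]:.1f}, {hit[1]:.1f})")

    samples, tangents = resample_path(path.points, spec.spacing)
    closed = _is_closed(path.points, spec.spacing) and len(samples) > 3
    if closed and np.linalg.norm(samples[-1] - samples[0]) < spec.spacing / 2:
        samples, tangents = samples[:-1], tangents[:-1]
    n = len(samples)
    if n < 2:
        raise StrokeError("stroke too short for a single fiber segment")

    # layer policy: auto starts front and jumps periodically (seeded)
    layers = []
    if path.layer == "auto":
        current = 0
        for i in range(n):
            if i > 0 and i % defaults.LAYER_JUMP_PERIOD == 0:
                others = [l for l in (0, 1, 2) if l != current]
                current = int(scene.world.rng.choice(others))
            layers.append(current)
    else:
        layers = [int(path.layer)] * n

    ids = []
    for i in range(n):
        angle = float(np.arctan2(tangents[i, 1], tangents[i, 0])) \
            + i * spec.subunit_rotation
        body = scene._create_body(ing, samples[i], angle=angle, layer=layers[i])
        ids.append(body.id)
    for a, b in zip(ids, ids[1:] + ([ids[0]] if closed else [])):
        scene.world.bodies[a].no_collide.add(b)
        scene.world.bodies[b].no_collide.add(a)
    hinges, springs = _chain_constraints(ids, samples, spec.spacing,
                                         spec.n_springs, closed)
    for c in hinges + springs:
        scene.world.add_constraint(c)
    chain = FiberChain(ingredient=ingredient_name, subunit_ids=ids,
                       hinges=hinges, springs=springs, layer_assignment=layers,
                       closed=closed, wrap_springs=closed, spacing=spec.spacing)
    scene.fiber_chains.append(chain)
    return chain


def draw_membrane(scene, ingredient_name: str, path: StrokePath) -> MembraneChain:
    """Instantiate a membrane chain; closed strokes become clockwise vesicles."""
    ing = scene.palette[ingredient_name]
    if ing.kind != "fiber":
        raise StrokeError(f"{ingredient_name!r} is not a membrane fiber ingredient")
    spec = ing.fiber
    spacing = spec.spacing
    thickness = min(ing.main_collider.height, ing.main_collider.width) \
        if hasattr(ing.main_collider, "height") else 2 * ing.main_collider.radius

    closed = _is_closed(path.points, spacing)
    samples, tangents = resample_path(path.points, spacing)
    if closed:
        if np.linalg.norm(samples[-1] - samples[0]) < spacing / 2:
            samples, tangents = samples[:-1], tangents[:-1]
        if len(samples) < 3:
            raise StrokeError("closed membrane needs >= 3 segments")
        ring = LineString(np.vstack([samples, samples[:1]]))
        if not ring.is_simple:
            raise StrokeError("closed membrane stroke self-intersects")
        if polygon_area(samples) > 0:          # counter-clockwise: reverse
            samples = samples[::-1].copy()
            tangents = -tangents[::-1].copy()
    if len(samples) < 2:
        raise StrokeError("stroke too short for a membrane segment")

    layer = 0 if path.layer == "auto" else int(path.layer)
    spacer_r = thickness / 2
    ids = []
    for i in range(len(samples)):
        angle = float(np.arctan2(tangents[i, 1], tangents[i, 0]))
        body = scene._create_body(ing, samples[i], angle=angle, layer=layer,
                                  collision_class="membrane")
        for sy in (1.0, -1.0):
            body.fixtures.append(Fixture(
                Circle(center=np.array([0.0, sy * (thickness / 2 + spacer_r)]),
                       radius=spacer_r, collision_class="membrane"),
                "membrane"))
        ids.append(body.id)
    for a, b in zip(ids, ids[1:] + ([ids[0]] if closed else [])):
        scene.world.bodies[a].no_collide.add(b)
        scene.world.bodies[b].no_collide.add(a)
    n_springs = defaults.SPRING_PRESETS["membrane"]
    hinges, springs = _chain_constraints(ids, samples, spacing, n_springs, closed)
    for c in hinges + springs:
        scene.world.add_constraint(c)

    chain = MembraneChain(ingredient=ingredient_name, segment_ids=ids,
                          hinges=hinges, springs=springs, closed=closed,
                          spacing=spacing, thickness=thickness)
    if closed:
        chain.interior_triangles = triangulate(Contour(samples, closed=True))
        chain.compartment = scene.register_compartment(chain)
    else:
        for end in (ids[0], ids[-1]):
            scene.pin(end)
            chain.end_pins.append(end)
    scene.membrane_chains.append(chain)
    scene.world.touch()
    return chain


def attach_to_membrane(scene, instance_id: int, chain: MembraneChain,
                       arc_position: float) -> Rail:
    """Attach a painted membrane-bound protein to a membrane chain.

    ``arc_position`` is the arc length (nm) along the chain from its first
    segment. The protein is posed with its exterior side facing outward
    (clockwise vesicles) / left of the drawing direction (open membranes).
    """
    body = scene.world.bodies[instance_id]
    ing = scene.palette[body.ingredient]
    if ing.kind != "membrane_bound":
        raise IngredientError(f"{body.ingredient!r} is not membrane-bound")
    pts, closed = chain.rail_points(scene.world)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]) if closed else pts,
                                 axis=0), axis=1)
    total = float(seg.sum())
    if closed:
        arc_position %= total
    elif arc_position < 0 or arc_position > total:
        raise StrokeError("placement beyond open membrane end (detached)")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    k = int(np.searchsorted(cum, arc_position, side="right") - 1)
    k = min(k, len(seg) - 1)
    t = (arc_position - cum[k]) / max(seg[k], 1e-12)
    nxt = (k + 1) % len(pts)
    foot = pts[k] + t * (pts[nxt] - pts[k])
    tangent = (pts[nxt] - pts[k]) / max(seg[k], 1e-12)
    # clockwise traversal: the left normal points outward (exterior side)
    normal = np.array([-tangent[1], tangent[0]])
    binding = ing.binding
    body.position[:] = foot + normal * binding.surface_offset
    body.angle = float(np.arctan2(tangent[1], tangent[0])) + binding.rotation
    rail = Rail(body=instance_id, chain=chain,
                surface_offset=binding.surface_offset,
                rotation=binding.rotation, side=1.0)
    scene.world.add_constraint(rail)
    return rail
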