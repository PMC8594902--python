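"""Scene state and the painting toolset over the physics world.

A Scene owns the ingredient palette, the physics world, painted instances,
groups, lock regions, live measurements and backgrounds, and implements the
interactive verbs (paint, erase, pin, pin-to, group/stamp, lock/unlock,
nudge, measure) headlessly and deterministically.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point
from shapely.geometry import Polygon as ShapelyPolygon

from . import defaults
from .geometry import Polygon, graham_hull, mean_shift_clusters
from .ingredients import Ingredient
from .physics import (
    CollisionMatrix,
    Fixture,
    PinTo,
    RigidBody,
    World,
    WorldConfig,
)
from .strokes import FiberChain, MembraneChain
from . import strokes as _strokes

__all__ = ["Scene", "Group", "LockRegion", "Background", "Measurement",
           "SceneError"]


class SceneError(ValueError):
    pass


@dataclass
class Group:
    """A reusable brush: member ingredient names with poses relative to the
    group centroid, plus internal distance constraints."""

    id: int
    members: list[tuple[str, np.ndarray, float]]   # (ingredient, offset, angle)
    pin_tos: list[tuple[int, int, np.ndarray, np.ndarray, float]] = \
        field(default_factory=list)                # (ia, ib, la, lb, dist)


@dataclass
class LockRegion:
    id: int
    member_ids: list[int]
    hulls: list[Polygon]
    hull_body_id: int | None = None


@dataclass
class Background:
    id: int
    image_ref: str
    nm_per_pixel: float
    opacity: float = 1.0
    rotation: float = 0.0
    z_order: int = 0

    def __post_init__(self):
        if self.nm_per_pixel <= 0:
            raise SceneError("background nm_per_pixel must be > 0")
        if not 0.0 <= self.opacity <= 1.0:
            raise SceneError("background opacity must be in [0, 1]")


@dataclass
class Measurement:
    id: int
    body_a: int
    body_b: int
    value: float = 0.0


class Scene:
    def __init__(self, canvas=(400.0, 400.0),
                 background_color=(40, 45, 60),
                 config: WorldConfig | None = None,
                 matrix: CollisionMatrix | None = None):
        self.canvas = (float(canvas[0]), float(canvas[1]))
        self.background_color = tuple(background_color)
        self.world = World(config=config, matrix=matrix)
        self.palette: dict[str, Ingredient] = {}
        self.instances: dict[int, str] = {}
        self.groups: dict[int, Group] = {}
        self.lock_regions: dict[int, LockRegion] = {}
        self.measurements: dict[int, Measurement] = {}
        self.backgrounds: dict[int, Background] = {}
        self.fiber_chains: list[FiberChain] = []
        self.membrane_chains: list[MembraneChain] = []
        self.compartments: dict[str, MembraneChain] = {}
        self._counter = 0

    # -- palette ------------------------------------------------------------

    def add_ingredient(self, ingredient: Ingredient) -> None:
        self.palette[ingredient.name] = ingredient

    def copy_number(self, ingredient_name: str) -> int:
        if ingredient_name not in self.palette:
            raise SceneError(f"unknown ingredient {ingredient_name!r}")
        return sum(1 for n in self.instances.values() if n == ingredient_name)

    # -- low-level body creation -------------------------------------------

    def _create_body(self, ing: Ingredient, position, angle: float = 0.0,
                     layer: int = 0, collision_class: str | None = None,
                     body_id: int | None = None) -> RigidBody:
        fixtures = [Fixture(shape, shape.collision_class)
                    for shape in ing.all_colliders()]
        cls = collision_class or ("fiber" if ing.kind == "fiber" else "protein")
        if collision_class == "membrane":
            fixtures = [Fixture(f.shape, "membrane") for f in fixtures]
        body = self.world.add_body(ing.name, position, angle=angle, layer=layer,
                                   fixtures=fixtures, collision_class=cls,
                                   body_id=body_id)
        self.instances[body.id] = ing.name
        return body

    def _next(self) -> int:
        self._counter += 1
        return self._counter

    # -- painting -----------------------------------------------------------

    def paint(self, ingredient_name: str, position, layer: int = 0,
              angle: float = 0.0, settle: bool = True) -> int:
        """Paint one instance; a bounded local settle resolves overlaps
        without disturbing pre-existing bodies."""
        if ingredient_name not in self.palette:
            raise SceneError(f"unknown ingredient {ingredient_name!r}")
        position = np.asarray(position, dtype=float)
        w, h = self.canvas
        if not (-w / 2 <= position[0] <= w / 2 and -h / 2 <= position[1] <= h / 2):
            raise SceneError(f"position {position} outside canvas")
        ing = self.palette[ingredient_name]
        if ing.kind == "membrane_bound" and not self._membrane_under(position):
            warnings.warn("membrane-bound ingredient painted with no membrane "
                          "under it; placed as a free body", stacklevel=2)
        body = self._create_body(ing, position, angle=angle, layer=layer)
        if settle:
            self._local_settle([body.id])
        self.update_measurements()
        return body.id

    def _membrane_under(self, position, tolerance: float = 10.0) -> bool:
        for chain in self.membrane_chains:
            pts, _ = chain.rail_points(self.world)
            if np.min(np.linalg.norm(pts - position, axis=1)) < tolerance:
                return True
        return False

    def _local_settle(self, new_ids: list[int],
                      steps: int = defaults.LOCAL_SETTLE_STEPS) -> None:
        """Settle with every pre-existing body frozen: the fresh bodies take
        100% of any push-out, old bodies stay put."""
        frozen = []
        for bid, b in self.world.bodies.items():
            if bid not in new_ids and not (b.locked or b.pinned):
                b.locked = True
                frozen.append(b)
        self.world.touch()
        try:
            self.world.settle(max_steps=steps)
        finally:
            for b in frozen:
                b.locked = False
            self.world.touch()

    # -- strokes (delegates) ------------------------------------------------

    def draw_fiber(self, ingredient_name: str, path) -> FiberChain:
        chain = _strokes.draw_fiber(self, ingredient_name, path)
        self.update_measurements()
        return chain

    def draw_membrane(self, ingredient_name: str, path) -> MembraneChain:
        chain = _strokes.draw_membrane(self, ingredient_name, path)
        self.update_measurements()
        return chain

    def attach_to_membrane(self, instance_id: int, chain: MembraneChain,
                           arc_position: float):
        return _strokes.attach_to_membrane(self, instance_id, chain, arc_position)

    def register_compartment(self, chain: MembraneChain) -> str:
        name = f"compartment_{len(self.compartments)}"
        self.compartments[name] = chain
        return name

    # -- erase --------------------------------------------------------------

    def erase(self, selector: int | str) -> int:
        """Remove one instance (by id) or all instances of an ingredient."""
        if isinstance(selector, str):
            if selector not in self.palette:
                raise SceneError(f"unknown ingredient {selector!r}")
            ids = [bid for bid, name in self.instances.items() if name == selector]
        else:
            if selector not in self.instances:
                raise SceneError(f"unknown instance {selector!r}")
            ids = [selector]
        for bid in ids:
            self._erase_one(bid)
        self.update_measurements()
        return len(ids)

    def _erase_one(self, bid: int) -> None:
        self.world.remove_body(bid)
        del self.instances[bid]
        self.measurements = {mid: m for mid, m in self.measurements.items()
                             if bid not in (m.body_a, m.body_b)}
        for chain in list(self.fiber_chains):
            if bid in chain.subunit_ids:
                self._split_fiber_chain(chain, bid)
        for chain in list(self.membrane_chains):
            if bid in chain.segment_ids:
                self._split_membrane_chain(chain, bid)
        for region in list(self.lock_regions.values()):
            if bid in region.member_ids:
                region.member_ids.remove(bid)
                self._recompute_lock_hulls(region)

    def _remove_chain_constraints(self, chain) -> None:
        doomed = set(map(id, chain.hinges + chain.springs))
        self.world.constraints = [c for c in self.world.constraints
                                  if id(c) not in doomed]
        self.world.touch()

    def _split_fiber_chain(self, chain: FiberChain, removed: int) -> None:
        """Erasing a middle subunit splits the chain into two valid chains."""
        self._remove_chain_constraints(chain)
        self.fiber_chains.remove(chain)
        ids = [i for i in chain.subunit_ids if i != removed]
        k = chain.subunit_ids.index(removed)
        parts = [chain.subunit_ids[:k], chain.subunit_ids[k + 1:]]
        if chain.closed:  # ring opens into a single chain
            parts = [parts[1] + parts[0]]
        spec = self.palette[chain.ingredient].fiber
        for part in parts:
            if len(part) < 2:
                continue
            pos = np.array([self.world.bodies[i].position for i in part])
            hinges, springs = _strokes._chain_constraints(
                part, pos, spec.spacing, spec.n_springs, closed=False)
            for c in hinges + springs:
                self.world.add_constraint(c)
            self.fiber_chains.append(FiberChain(
                ingredient=chain.ingredient, subunit_ids=part, hinges=hinges,
                springs=springs,
                layer_assignment=[self.world.bodies[i].layer for i in part],
                closed=False, spacing=chain.spacing))

    def _split_membrane_chain(self, chain: MembraneChain, removed: int) -> None:
        self._remove_chain_constraints(chain)
        self.membrane_chains.remove(chain)
        if chain.compartment:
            self.compartments.pop(chain.compartment, None)
        k = chain.segment_ids.index(removed)
        parts = [chain.segment_ids[:k], chain.segment_ids[k + 1:]]
        if chain.closed:
            parts = [parts[1] + parts[0]]
        n_springs = defaults.SPRING_PRESETS["membrane"]
        for part in parts:
            if len(part) < 2:
                continue
            pos = np.array([self.world.bodies[i].position for i in part])
            hinges, springs = _strokes._chain_constraints(
                part, pos, chain.spacing, n_springs, closed=False)
            for c in hinges + springs:
                self.world.add_constraint(c)
            piece = MembraneChain(ingredient=chain.ingredient, segment_ids=part,
                                  hinges=hinges, springs=springs, closed=False,
                                  spacing=chain.spacing, thickness=chain.thickness)
            for end in (part[0], part[-1]):
                self.pin(end)
                piece.end_pins.append(end)
            self.membrane_chains.append(piece)

    # -- pinning ------------------------------------------------------------

    def pin(self, selector: int) -> None:
        """Freeze an instance (or every member of its group stamp) in place."""
        for b in self._select(selector):
            b.pinned = True
        self.world.touch()

    def unpin(self, selector: int) -> None:
        for b in self._select(selector):
            b.pinned = False
        self.world.touch()

    def pin_to(self, a: int, local_a, b: int, local_b) -> PinTo:
        """Constrain the distance between local points of two instances to its
        current value (isotropic: no angular coupling)."""
        if a == b:
            raise SceneError("cannot pin an instance to itself")
        for bid in (a, b):
            if bid not in self.instances:
                raise SceneError(f"unknown instance {bid!r}")
        ba, bb = self.world.bodies[a], self.world.bodies[b]
        la = np.asarray(local_a, dtype=float)
        lb = np.asarray(local_b, dtype=float)
        wa = ba.position + _rot(la, ba.angle)
        wb = bb.position + _rot(lb, bb.angle)
        c = PinTo(body_a=a, body_b=b, local_a=la, local_b=lb,
                  distance=float(np.linalg.norm(wa - wb)))
        self.world.add_constraint(c)
        return c

    def _select(self, selector: int) -> list[RigidBody]:
        if selector in self.instances:
            body = self.world.bodies[selector]
            if body.group_stamp is not None:
                return [b for b in self.world.bodies.values()
                        if b.group_stamp == body.group_stamp]
            return [body]
        raise SceneError(f"unknown instance {selector!r}")

    # -- groups -------------------------------------------------------------

    def group(self, instance_ids: list[int]) -> Group:
        if not instance_ids:
            raise SceneError("empty selection for group")
        for bid in instance_ids:
            if bid not in self.instances:
                raise SceneError(f"unknown instance {bid!r}")
        centers = np.array([self.world.bodies[i].position for i in instance_ids])
        centroid = centers.mean(axis=0)
        members = [(self.instances[i], self.world.bodies[i].position - centroid,
                    self.world.bodies[i].angle) for i in instance_ids]
        pin_tos = []
        idx = {bid: k for k, bid in enumerate(instance_ids)}
        for c in self.world.constraints:
            if isinstance(c, PinTo) and c.body_a in idx and c.body_b in idx:
                pin_tos.append((idx[c.body_a], idx[c.body_b],
                                c.local_a.copy(), c.local_b.copy(), c.distance))
        g = Group(id=self._next(), members=members, pin_tos=pin_tos)
        self.groups[g.id] = g
        return g

    def stamp(self, group: Group | int, position, angle: float = 0.0) -> list[int]:
        """Instantiate a group at a new pose; members stay individually
        dynamic but do not collide with their stamp siblings."""
        g = self.groups[group] if isinstance(group, int) else group
        position = np.asarray(position, dtype=float)
        stamp_id = self._next()
        new_ids = []
        for name, offset, member_angle in g.members:
            pos = position + _rot(np.asarray(offset), angle)
            body = self._create_body(self.palette[name], pos,
                                     angle=member_angle + angle)
            body.group_stamp = stamp_id
            new_ids.append(body.id)
        for ia, ib, la, lb, dist in g.pin_tos:
            self.world.add_constraint(PinTo(body_a=new_ids[ia], body_b=new_ids[ib],
                                            local_a=la.copy(), local_b=lb.copy(),
                                            distance=dist))
        self._local_settle(new_ids)
        self.update_measurements()
        return new_ids

    # -- locking ------------------------------------------------------------

    def lock(self, instance_ids: list[int]) -> LockRegion:
        """Turn physics off within a selection and represent it by dilated
        Graham hulls over mean-shift clusters of member centers."""
        if not instance_ids:
            raise SceneError("empty selection for lock")
        already = [bid for bid in instance_ids
                   if self.world.bodies[bid].lock_id is not None]
        if already:
            if len(already) == len(instance_ids):
                warnings.warn("selection already locked; no-op", stacklevel=2)
                region_id = self.world.bodies[already[0]].lock_id
                return self.lock_regions[region_id]
            raise SceneError("selection mixes locked and unlocked instances")
        region = LockRegion(id=self._next(), member_ids=list(instance_ids),
                            hulls=[])
        for bid in instance_ids:
            body = self.world.bodies[bid]
            body.locked = True
            body.lock_id = region.id
        self.lock_regions[region.id] = region
        self._recompute_lock_hulls(region)
        return region

    def _recompute_lock_hulls(self, region: LockRegion) -> None:
        if region.hull_body_id is not None:
            self.world.bodies.pop(region.hull_body_id, None)
            region.hull_body_id = None
        if not region.member_ids:
            del self.lock_regions[region.id]
            return
        centers = np.array([self.world.bodies[i].position
                            for i in region.member_ids])
        clusters = mean_shift_clusters(centers,
                                       bandwidth=defaults.LOCK_BANDWIDTH_NM)
        hulls = []
        for cluster in clusters:
            pts = centers[cluster]
            r = max(self.world.bodies[region.member_ids[i]].bound_radius()
                    for i in cluster)
            if len(pts) >= 3:
                try:
                    base = ShapelyPolygon(graham_hull(pts).vertices)
                except Exception:
                    base = Point(pts.mean(axis=0)).buffer(
                        float(np.linalg.norm(pts - pts.mean(axis=0),
                                             axis=1).max()))
            elif len(pts) == 2:
                from shapely.geometry import LineString
                base = LineString(pts)
            else:
                base = Point(pts[0])
            dilated = base.buffer(max(r, 0.1),
                                  quad_segs=defaults.HULL_BUFFER_QUAD_SEGS)
            verts = np.array(dilated.exterior.coords)[:-1]
            hulls.append(Polygon(verts, collision_class="lock"))
        region.hulls = hulls
        hull_body = self.world.add_body(
            f"__lock_{region.id}", centers.mean(axis=0) * 0.0,
            fixtures=[Fixture(h, "lock") for h in hulls],
            collision_class="lock")
        hull_body.locked = True
        hull_body.region_id = region.id
        region.hull_body_id = hull_body.id
        self.world.touch()

    def unlock(self, region: LockRegion | int) -> None:
        r = self.lock_regions[region] if isinstance(region, int) else region
        for bid in r.member_ids:
            body = self.world.bodies[bid]
            body.locked = False
            body.lock_id = None
        if r.hull_body_id is not None:
            self.world.bodies.pop(r.hull_body_id, None)
        del self.lock_regions[r.id]
        self.world.touch()

    # -- measurement --------------------------------------------------------

    def measure(self, a: int, b: int) -> float:
        for bid in (a, b):
            if bid not in self.instances:
                raise SceneError(f"unknown instance {bid!r}")
        m = Measurement(id=self._next(), body_a=a, body_b=b)
        m.value = self._distance(a, b)
        self.measurements[m.id] = m
        return m.value

    def _distance(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.world.bodies[a].position
                                    - self.world.bodies[b].position))

    def update_measurements(self) -> None:
        for m in self.measurements.values():
            m.value = self._distance(m.body_a, m.body_b)

    # -- backgrounds --------------------------------------------------------

    def set_background(self, image_ref: str, nm_per_pixel: float,
                       opacity: float = 1.0, rotation: float = 0.0,
                       z_order: int | None = None) -> int:
        bg = Background(id=self._next(), image_ref=image_ref,
                        nm_per_pixel=nm_per_pixel, opacity=opacity,
                        rotation=rotation,
                        z_order=len(self.backgrounds) if z_order is None
                        else z_order)
        self.backgrounds[bg.id] = bg
        return bg.id

    # -- nudge --------------------------------------------------------------

    def nudge(self, selector: int, delta) -> np.ndarray:
        """Rigidly translate an instance, stamp, or lock region (hulls and
        pins included), then locally settle the surroundings."""
        delta = np.asarray(delta, dtype=float)
        bodies = self._nudge_selection(selector)
        for b in bodies:
            b.position += delta
        self.world.touch()
        moved = [b.id for b in bodies]
        frozen = []
        for bid, b in self.world.bodies.items():
            if bid in moved and not (b.locked or b.pinned):
                b.locked = True
                frozen.append(b)
        try:
            self.world.settle(max_steps=defaults.LOCAL_SETTLE_STEPS)
        finally:
            for b in frozen:
                b.locked = False
            self.world.touch()
        self.update_measurements()
        return bodies[0].position.copy()

    def _nudge_selection(self, selector: int) -> list[RigidBody]:
        if selector in self.lock_regions:
            region = self.lock_regions[selector]
            ids = list(region.member_ids)
            if region.hull_body_id is not None:
                ids.append(region.hull_body_id)
            return [self.world.bodies[i] for i in ids]
        return self._select(selector)

    # -- steps --------------------------------------------------------------

    def step(self, n: int = 1) -> float:
        corr = self.world.step(n)
        self.update_measurements()
        return corr

    def settle(self, max_steps: int = 500) -> int:
        n = self.world.settle(max_steps=max_steps)
        self.update_measurements()
        return n


def _rot(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])
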