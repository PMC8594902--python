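"""Deterministic, seedable 2.5D constraint world.

Position-based dynamics: per step, collision candidates are gathered once,
then a fixed number of solver iterations interleave pairwise overlap
resolution (Gauss-Seidel over pairs) with batched Jacobi projection of
hinge, spring, rail and distance constraints. Locked and pinned bodies have
infinite mass. Everything is reproducible from (scene, config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .geometry import Circle, ColliderShape, Polygon, Rect

__all__ = [
    "Fixture",
    "RigidBody",
    "CollisionMatrix",
    "WorldConfig",
    "World",
    "Hinge",
    "Spring",
    "Rail",
    "PinTo",
    "SimulationError",
    "DetachedError",
    "collidable",
    "resolve_pair",
]

_EPS = 1e-12


class SimulationError(RuntimeError):
    pass


class DetachedError(SimulationError):
    """A railed protein strayed more than one segment length from its membrane."""


# ---------------------------------------------------------------------------
# bodies and filtering
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    shape: ColliderShape
    collision_class: str


@dataclass
class RigidBody:
    id: int
    ingredient: str
    position: np.ndarray
    angle: float = 0.0
    layer: int = 0
    collision_class: str = "protein"
    locked: bool = False
    pinned: bool = False
    group_stamp: int | None = None
    lock_id: int | None = None
    fixtures: list[Fixture] = field(default_factory=list)
    no_collide: set[int] = field(default_factory=set)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).copy()
        if self.layer not in (0, 1, 2):
            raise ValueError("layer must be 0, 1 or 2")

    @property
    def mass(self) -> float:
        """Mass proportional to the main (first) collider area."""
        if not self.fixtures:
            return 1.0
        return max(self.fixtures[0].shape.area(), _EPS)

    @property
    def inv_mass(self) -> float:
        return 0.0 if (self.locked or self.pinned) else 1.0 / self.mass

    @property
    def inv_inertia(self) -> float:
        if self.locked or self.pinned or not self.fixtures:
            return 0.0
        shape = self.fixtures[0].shape
        if isinstance(shape, Circle):
            k2 = shape.radius**2 / 2
        elif isinstance(shape, Rect):
            k2 = (shape.width**2 + shape.height**2) / 12
        else:
            k2 = shape.bbox_radius() ** 2 / 2
        return 1.0 / max(self.mass * k2, _EPS)

    def bound_radius(self) -> float:
        if not self.fixtures:
            return 0.0
        return max(f.shape.bbox_radius() for f in self.fixtures)


_CLASS_TOGGLE = {
    ("protein", "protein"): "protein_protein",
    ("fiber", "protein"): "fiber_protein",
    ("fiber", "fiber"): "fiber_fiber",
    ("membrane", "membrane"): "membrane_membrane",
}


@dataclass
class CollisionMatrix:
    """Class-pair toggles plus the front-layer rule.

    Cross pairs not in the toggle list (protein-membrane, fiber-membrane) are
    off: the main collider of a membrane protein only sees proteins and
    fibers, and fibers avoid membranes at draw time. Lock hulls collide with
    every non-lock class.
    """

    protein_protein: bool = True
    fiber_protein: bool = True
    fiber_fiber: bool = True
    membrane_membrane: bool = True

    def allowed(self, class_a: str, class_b: str) -> bool:
        if "lock" in (class_a, class_b):
            return class_a != class_b
        key = tuple(sorted((class_a, class_b)))
        toggle = _CLASS_TOGGLE.get(key)
        return bool(getattr(self, toggle)) if toggle else False


def collidable(a: RigidBody, b: RigidBody, matrix: CollisionMatrix) -> bool:
    """Body-level collision filter (symmetric)."""
    if a.id == b.id:
        return False
    # lock members have their physics turned off; only their hull collides
    for x, y in ((a, b), (b, a)):
        if x.collision_class == "lock":
            if y.lock_id is not None and y.lock_id == getattr(x, "region_id", None):
                return False
    if a.collision_class != "lock" and a.lock_id is not None:
        return False
    if b.collision_class != "lock" and b.lock_id is not None:
        return False
    if (a.locked or a.pinned) and (b.locked or b.pinned):
        return False
    if a.layer != b.layer and 0 in (a.layer, b.layer):
        return False
    if a.group_stamp is not None and a.group_stamp == b.group_stamp:
        return False
    if b.id in a.no_collide or a.id in b.no_collide:
        return False
    return any(matrix.allowed(fa.collision_class, fb.collision_class)
               for fa in a.fixtures for fb in b.fixtures)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@dataclass
class Hinge:
    """Anchor-coincidence constraint allowing free relative rotation."""

    body_a: int
    body_b: int
    anchor_a: np.ndarray     # local, nm
    anchor_b: np.ndarray
    angle_limit: float | None = None


@dataclass
class Spring:
    """Center-to-center distance constraint driven toward rest_length."""

    body_a: int
    body_b: int
    rest_length: float
    stiffness: float = defaults.SPRING_STIFFNESS


@dataclass
class PinTo:
    """Isotropic distance constraint between local points of two bodies."""

    body_a: int
    body_b: int
    local_a: np.ndarray
    local_b: np.ndarray
    distance: float


@dataclass
class Rail:
    """Wheels-on-a-rail constraint keeping a protein embedded in a membrane.

    ``chain`` must expose ``rail_points(world) -> (points, closed)`` giving
    the current membrane centerline, plus ``spacing``. ``side`` flips which
    side of the polyline is treated as exterior (+1: left of travel).
    """

    body: int
    chain: object
    surface_offset: float = 0.0
    rotation: float = 0.0
    side: float = 1.0


# ---------------------------------------------------------------------------
# narrow phase
# ---------------------------------------------------------------------------

def _world_shape(fix: Fixture, pos: np.ndarray, ang: float):
    """Return ("circle", center, r) or ("poly", verts) in world coordinates."""
    c, s = np.cos(ang), np.sin(ang)
    rot = np.array([[c, -s], [s, c]])
    shape = fix.shape
    if isinstance(shape, Circle):
        return ("circle", pos + rot @ shape.center, shape.radius)
    if isinstance(shape, Rect):
        world = Rect(center=pos + rot @ shape.center, width=shape.width,
                     height=shape.height, angle=shape.angle + ang)
        return ("poly", world.corners())
    return ("poly", (rot @ shape.vertices.T).T + pos)


def _project(verts: np.ndarray, axis: np.ndarray):
    p = verts @ axis
    return p.min(), p.max()


def _poly_axes(verts: np.ndarray) -> np.ndarray:
    edges = np.roll(verts, -1, axis=0) - verts
    normals = np.column_stack([-edges[:, 1], edges[:, 0]])
    lengths = np.linalg.norm(normals, axis=1)
    return normals[lengths > _EPS] / lengths[lengths > _EPS, None]


def _sat(shape_a, shape_b) -> np.ndarray | None:
    """Minimum translation vector moving shape A out of shape B (None if apart)."""
    kind_a = shape_a[0]
    kind_b = shape_b[0]
    if kind_a == "circle" and kind_b == "circle":
        _, ca, ra = shape_a
        _, cb, rb = shape_b
        d = ca - cb
        dist = float(np.linalg.norm(d))
        pen = ra + rb - dist
        if pen <= 0:
            return None
        n = d / dist if dist > _EPS else np.array([1.0, 0.0])
        return n * pen

    axes = []
    if kind_a == "poly":
        axes.append(_poly_axes(shape_a[1]))
    if kind_b == "poly":
        axes.append(_poly_axes(shape_b[1]))
    ca = shape_a[1] if kind_a == "circle" else shape_a[1].mean(axis=0)
    cb = shape_b[1] if kind_b == "circle" else shape_b[1].mean(axis=0)
    for circ, poly in (((shape_a, shape_b) if kind_a == "circle" else
                        (shape_b, shape_a)),) if "circle" in (kind_a, kind_b) else ():
        center = circ[1]
        verts = poly[1]
        nearest = verts[np.argmin(np.linalg.norm(verts - center, axis=1))]
        d = center - nearest
        norm = np.linalg.norm(d)
        if norm > _EPS:
            axes.append((d / norm)[None, :])
    axes = np.vstack(axes)

    best_pen = np.inf
    best_axis = None
    for axis in axes:
        if kind_a == "circle":
            pa = float(shape_a[1] @ axis)
            lo_a, hi_a = pa - shape_a[2], pa + shape_a[2]
        else:
            lo_a, hi_a = _project(shape_a[1], axis)
        if kind_b == "circle":
            pb = float(shape_b[1] @ axis)
            lo_b, hi_b = pb - shape_b[2], pb + shape_b[2]
        else:
            lo_b, hi_b = _project(shape_b[1], axis)
        overlap = min(hi_a, hi_b) - max(lo_a, lo_b)
        if overlap <= 0:
            return None
        if overlap < best_pen:
            best_pen = overlap
            best_axis = axis
    n = best_axis if float((ca - cb) @ best_axis) >= 0 else -best_axis
    return n * best_pen


def resolve_pair(a: RigidBody, b: RigidBody) -> dict[int, np.ndarray]:
    """Positional corrections separating two overlapping bodies.

    The minimum translation vector is split by inverse mass (locked or pinned
    bodies absorb nothing); rotation is untouched. Returns {body id: delta}.
    """
    total_a = np.zeros(2)
    total_b = np.zeros(2)
    for fa in a.fixtures:
        sa = _world_shape(fa, a.position, a.angle)
        for fb in b.fixtures:
            sb = _world_shape(fb, b.position, b.angle)
            mtv = _sat(sa, sb)
            if mtv is None:
                continue
            wa, wb = a.inv_mass, b.inv_mass
            wsum = wa + wb
            if wsum <= 0:
                continue
            total_a += mtv * (wa / wsum)
            total_b -= mtv * (wb / wsum)
    return {a.id: total_a, b.id: total_b}


# ---------------------------------------------------------------------------
# world
# ---------------------------------------------------------------------------

@dataclass
class WorldConfig:
    dt: float = defaults.DT
    solver_iterations: int = defaults.SOLVER_ITERATIONS
    position_tolerance: float = defaults.POSITION_TOLERANCE_NM
    rng_seed: int = 0
    diffusion_scale: float = defaults.DIFFUSION_SCALE
    diffusion_enabled: bool = False

    def __post_init__(self):
        if self.dt <= 0 or self.solver_iterations < 1:
            raise ValueError("dt must be > 0 and solver_iterations >= 1")


def _rotate(vectors: np.ndarray, angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    x, y = vectors[:, 0], vectors[:, 1]
    return np.column_stack([c * x - s * y, s * x + c * y])


class World:
    """2.5D physics state: rigid bodies on 3 depth layers plus constraints."""

    def __init__(self, config: WorldConfig | None = None,
                 matrix: CollisionMatrix | None = None):
        self.config = config or WorldConfig()
        self.matrix = matrix or CollisionMatrix()
        self.bodies: dict[int, RigidBody] = {}
        self.constraints: list = []
        self.rng = np.random.default_rng(self.config.rng_seed)
        self._next_id = 0
        self._dirty = True

    # -- body management ----------------------------------------------------

    def add_body(self, ingredient: str, position, angle: float = 0.0,
                 layer: int = 0, fixtures: list[Fixture] | None = None,
                 collision_class: str = "protein",
                 body_id: int | None = None) -> RigidBody:
        if body_id is not None:
            if body_id in self.bodies:
                raise ValueError(f"body id {body_id} already in use")
            self._next_id = max(self._next_id, body_id)
        body = RigidBody(id=self._next_id, ingredient=ingredient,
                         position=np.asarray(position, dtype=float),
                         angle=float(angle), layer=layer,
                         collision_class=collision_class,
                         fixtures=fixtures or [])
        self.bodies[body.id] = body
        self._next_id += 1
        self._dirty = True
        return body

    def remove_body(self, body_id: int) -> None:
        self.bodies.pop(body_id)
        self.constraints = [c for c in self.constraints
                            if body_id not in _constraint_bodies(c)]
        for b in self.bodies.values():
            b.no_collide.discard(body_id)
        self._dirty = True

    def add_constraint(self, constraint) -> None:
        self.constraints.append(constraint)
        self._dirty = True

    def remove_constraint(self, constraint) -> None:
        self.constraints.remove(constraint)
        self._dirty = True

    def touch(self) -> None:
        """Mark cached solver arrays stale (call after mutating bodies)."""
        self._dirty = True

    # -- cache --------------------------------------------------------------

    def _rebuild(self):
        self._order = sorted(self.bodies)
        self._index = {bid: i for i, bid in enumerate(self._order)}
        n = len(self._order)
        self._pos = np.zeros((n, 2))
        self._ang = np.zeros(n)
        self._wm = np.zeros(n)
        self._wi = np.zeros(n)
        self._area = np.ones(n)
        for i, bid in enumerate(self._order):
            b = self.bodies[bid]
            self._wm[i] = b.inv_mass
            self._wi[i] = b.inv_inertia
            self._area[i] = b.mass

        hinges = [c for c in self.constraints if isinstance(c, Hinge)]
        self._h_ia = np.array([self._index[h.body_a] for h in hinges], dtype=int)
        self._h_ib = np.array([self._index[h.body_b] for h in hinges], dtype=int)
        self._h_la = np.array([h.anchor_a for h in hinges], dtype=float).reshape(-1, 2)
        self._h_lb = np.array([h.anchor_b for h in hinges], dtype=float).reshape(-1, 2)

        springs = [c for c in self.constraints if isinstance(c, Spring)]
        self._s_ia = np.array([self._index[s.body_a] for s in springs], dtype=int)
        self._s_ib = np.array([self._index[s.body_b] for s in springs], dtype=int)
        self._s_rest = np.array([s.rest_length for s in springs], dtype=float)
        self._s_k = np.array([s.stiffness for s in springs], dtype=float)
        # Jacobi averaging: a body accumulating k corrections applies their mean
        self._h_count = np.maximum(np.bincount(
            np.concatenate([self._h_ia, self._h_ib]), minlength=n), 1)[:, None]
        self._s_count = np.maximum(np.bincount(
            np.concatenate([self._s_ia, self._s_ib]), minlength=n), 1)[:, None]

        self._pintos = [c for c in self.constraints if isinstance(c, PinTo)]
        self._rails = [c for c in self.constraints if isinstance(c, Rail)]
        self._dirty = False

    def _gather(self):
        for i, bid in enumerate(self._order):
            b = self.bodies[bid]
            self._pos[i] = b.position
            self._ang[i] = b.angle

    def _scatter(self):
        for i, bid in enumerate(self._order):
            b = self.bodies[bid]
            b.position[:] = self._pos[i]
            b.angle = float(self._ang[i])

    # -- solver pieces ------------------------------------------------------

    def _candidate_pairs(self) -> list[tuple[int, int]]:
        order = self._order
        bodies = [self.bodies[bid] for bid in order]
        radii = np.array([b.bound_radius() for b in bodies])
        if len(bodies) < 2:
            return []
        cell = max(2.0 * radii.max(), 1.0)
        margin = defaults.BROADPHASE_MARGIN_NM
        grid: dict[tuple[int, int], list[int]] = {}
        for i in range(len(bodies)):
            key = (int(np.floor(self._pos[i, 0] / cell)),
                   int(np.floor(self._pos[i, 1] / cell)))
            grid.setdefault(key, []).append(i)
        pairs = []
        seen = set()
        for (gx, gy), members in grid.items():
            neighborhood: list[int] = []
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    neighborhood.extend(grid.get((gx + dx, gy + dy), ()))
            for i in members:
                for j in neighborhood:
                    if j <= i or (i, j) in seen:
                        continue
                    seen.add((i, j))
                    if (np.linalg.norm(self._pos[i] - self._pos[j])
                            > radii[i] + radii[j] + margin):
                        continue
                    if collidable(bodies[i], bodies[j], self.matrix):
                        pairs.append((i, j))
        pairs.sort()
        return pairs

    def _solve_collisions(self, pairs) -> float:
        max_corr = 0.0
        bodies = [self.bodies[bid] for bid in self._order]
        for i, j in pairs:
            a, b = bodies[i], bodies[j]
            wa, wb = self._wm[i], self._wm[j]
            wsum = wa + wb
            if wsum <= 0:
                continue
            for fa in a.fixtures:
                sa = _world_shape(fa, self._pos[i], self._ang[i])
                for fb in b.fixtures:
                    if not self.matrix.allowed(fa.collision_class,
                                               fb.collision_class):
                        continue
                    sb = _world_shape(fb, self._pos[j], self._ang[j])
                    mtv = _sat(sa, sb)
                    if mtv is None:
                        continue
                    self._pos[i] += mtv * (wa / wsum)
                    self._pos[j] -= mtv * (wb / wsum)
                    max_corr = max(max_corr, float(np.linalg.norm(mtv)))
                    sa = _world_shape(fa, self._pos[i], self._ang[i])
        return max_corr

    def _solve_hinges(self) -> float:
        if len(self._h_ia) == 0:
            return 0.0
        ia, ib = self._h_ia, self._h_ib
        ra = _rotate(self._h_la, self._ang[ia])
        rb = _rotate(self._h_lb, self._ang[ib])
        d = (self._pos[ia] + ra) - (self._pos[ib] + rb)
        dist = np.linalg.norm(d, axis=1)
        n = d / np.maximum(dist, _EPS)[:, None]
        cross_a = ra[:, 0] * n[:, 1] - ra[:, 1] * n[:, 0]
        cross_b = rb[:, 0] * n[:, 1] - rb[:, 1] * n[:, 0]
        wa = self._wm[ia] + self._wi[ia] * cross_a**2
        wb = self._wm[ib] + self._wi[ib] * cross_b**2
        lam = np.where(wa + wb > 0, dist / np.maximum(wa + wb, _EPS), 0.0)
        lam = lam * defaults.HINGE_RELAXATION
        dpos = np.zeros_like(self._pos)
        dang = np.zeros_like(self._ang)
        np.add.at(dpos, ia, -(lam * self._wm[ia])[:, None] * n)
        np.add.at(dpos, ib, (lam * self._wm[ib])[:, None] * n)
        np.add.at(dang, ia, -lam * self._wi[ia] * cross_a)
        np.add.at(dang, ib, lam * self._wi[ib] * cross_b)
        self._pos += dpos / self._h_count
        self._ang += dang / self._h_count[:, 0]
        return float(np.max(lam * np.maximum(self._wm[ia], self._wm[ib])))

    def _solve_springs(self) -> float:
        if len(self._s_ia) == 0:
            return 0.0
        ia, ib = self._s_ia, self._s_ib
        d = self._pos[ia] - self._pos[ib]
        dist = np.linalg.norm(d, axis=1)
        n = d / np.maximum(dist, _EPS)[:, None]
        err = dist - self._s_rest
        wa, wb = self._wm[ia], self._wm[ib]
        wsum = np.maximum(wa + wb, _EPS)
        corr = self._s_k * err / wsum
        dpos = np.zeros_like(self._pos)
        np.add.at(dpos, ia, -(corr * wa)[:, None] * n)
        np.add.at(dpos, ib, (corr * wb)[:, None] * n)
        self._pos += dpos / self._s_count
        return float(np.max(np.abs(corr) * np.maximum(wa, wb)))

    def _apply_rail(self, rail: Rail) -> float:
        i = self._index[rail.body]
        if self._wm[i] <= 0:
            return 0.0
        points, closed = rail.chain.rail_points(self)
        spacing = rail.chain.spacing
        p = self._pos[i]
        seg_a = points
        seg_b = np.roll(points, -1, axis=0) if closed else points[1:]
        if not closed:
            seg_a = points[:-1]
        e = seg_b - seg_a
        el2 = np.maximum((e**2).sum(axis=1), _EPS)
        t = np.clip(((p - seg_a) * e).sum(axis=1) / el2, 0.0, 1.0)
        feet = seg_a + t[:, None] * e
        d2 = ((feet - p) ** 2).sum(axis=1)
        k = int(np.argmin(d2))
        foot = feet[k]
        if np.sqrt(d2[k]) > max(spacing, 1e-9) + abs(rail.surface_offset):
            raise DetachedError(
                f"body {rail.body} detached from membrane chain "
                f"(distance {np.sqrt(d2[k]):.2f} nm)")
        tangent = e[k] / np.sqrt(el2[k])
        normal = np.array([-tangent[1], tangent[0]]) * rail.side
        target = foot + normal * rail.surface_offset
        delta = (target - p) @ normal   # free sliding: correct normal only
        self._pos[i] += normal * delta
        self._ang[i] = float(np.arctan2(tangent[1], tangent[0])) + rail.rotation
        return abs(float(delta))

    def _solve_pintos(self) -> float:
        max_corr = 0.0
        for c in self._pintos:
            i, j = self._index[c.body_a], self._index[c.body_b]
            pa = self._pos[i] + _rotate(c.local_a[None, :], self._ang[[i]])[0]
            pb = self._pos[j] + _rotate(c.local_b[None, :], self._ang[[j]])[0]
            d = pa - pb
            dist = float(np.linalg.norm(d))
            n = d / dist if dist > _EPS else np.array([1.0, 0.0])
            err = dist - c.distance
            wa, wb = self._wm[i], self._wm[j]
            wsum = wa + wb
            if wsum <= 0:
                continue
            self._pos[i] -= n * err * (wa / wsum)
            self._pos[j] += n * err * (wb / wsum)
            max_corr = max(max_corr, abs(err))
        return max_corr

    # -- top-level ----------------------------------------------------------

    def diffuse_kick(self):
        """One Brownian kick for every free body (draws are flag-independent)."""
        n = len(self._order)
        disp = self.rng.normal(size=(n, 2))
        ang = self.rng.normal(size=n)
        free = (self._wm > 0).astype(float)
        std = np.sqrt(self.config.diffusion_scale / np.sqrt(self._area))
        self._pos += disp * (std * free)[:, None]
        self._ang += ang * defaults.ANGULAR_DIFFUSION / self._area**0.25 * free

    def step(self, n_steps: int = 1) -> float:
        """Advance the world; returns the last step's max correction (nm)."""
        if self._dirty:
            self._rebuild()
        self._gather()
        max_corr = 0.0
        for _ in range(n_steps):
            if self.config.diffusion_enabled:
                self.diffuse_kick()
            pairs = self._candidate_pairs()
            max_corr = 0.0
            for _ in range(self.config.solver_iterations):
                max_corr = max(max_corr, self._solve_collisions(pairs))
                max_corr = max(max_corr, self._solve_hinges())
                max_corr = max(max_corr, self._solve_springs())
                for rail in self._rails:
                    max_corr = max(max_corr, self._apply_rail(rail))
                max_corr = max(max_corr, self._solve_pintos())
            if not np.all(np.isfinite(self._pos)):
                bad = self._order[int(np.where(~np.isfinite(self._pos))[0][0])]
                raise SimulationError(f"simulation diverged: body {bad} "
                                      "has a non-finite position")
        self._scatter()
        return max_corr

    def settle(self, max_steps: int = 500, tol: float | None = None) -> int:
        """Step until the max correction drops below tolerance; returns steps."""
        tol = self.config.position_tolerance if tol is None else tol
        for i in range(max_steps):
            if self.step(1) < tol:
                return i + 1
        return max_steps


def _constraint_bodies(c) -> tuple[int, ...]:
    if isinstance(c, (Hinge, Spring, PinTo)):
        return (c.body_a, c.body_b)
    if isinstance(c, Rail):
        return (c.body,)
    return ()
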