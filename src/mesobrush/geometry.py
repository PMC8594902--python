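"""Pure 2D geometry kernel.

Contour extraction, covariance eigen-analysis, primitive collider selection,
Graham convex hulls, flat-kernel mean-shift clustering, ear-clipping
triangulation. All coordinates are nm, Y-up, origin at the sprite center.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from . import defaults

__all__ = [
    "Contour",
    "EigenFrame",
    "Circle",
    "Rect",
    "Polygon",
    "GeometryError",
    "extract_contour",
    "eigen_frame",
    "select_collider",
    "graham_hull",
    "mean_shift_clusters",
    "triangulate",
    "orientation",
    "polygon_area",
]

_EPS = 1e-12


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contour:
    """Ordered 2D vertex loop (or open chain) in nm, Y-up.

    Invariants: >= 3 vertices, no consecutive duplicates, simple when closed.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError("contour vertices must be an (n, 2) array")
        if len(v) < 3:
            raise GeometryError("contour needs at least 3 vertices")
        d = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(d < _EPS):
            raise GeometryError("contour has consecutive duplicate points")
        object.__setattr__(self, "vertices", v)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def area(self) -> float:
        """Absolute shoelace area (closed contours)."""
        return abs(_shoelace(self.vertices))


@dataclass(frozen=True)
class EigenFrame:
    """Principal frame of a vertex set: centroid, orthonormal axes, eigenvalues.

    ``axes[0]`` is the major axis (largest eigenvalue first); sign convention:
    the major axis has a non-negative X component (ties broken toward +Y), and
    the minor axis completes a right-handed frame.
    """

    center: np.ndarray
    axes: np.ndarray          # (2, 2), rows are unit vectors, major first
    eigenvalues: np.ndarray   # (2,), lam1 >= lam2 > 0, nm^2

    @property
    def ratio(self) -> float:
        return float(self.eigenvalues[0] / self.eigenvalues[1])

    @property
    def angle(self) -> float:
        """Angle of the major axis, rad."""
        return float(np.arctan2(self.axes[0, 1], self.axes[0, 0]))


@dataclass(frozen=True)
class Circle:
    center: np.ndarray
    radius: float
    collision_class: str = "protein"

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise GeometryError("circle radius must be > 0")

    def area(self) -> float:
        return float(np.pi * self.radius**2)

    def bbox_radius(self) -> float:
        return float(np.linalg.norm(self.center) + self.radius)


@dataclass(frozen=True)
class Rect:
    """Oriented rectangle: center, full width/height (width >= height), angle."""

    center: np.ndarray
    width: float
    height: float
    angle: float = 0.0
    collision_class: str = "protein"

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not (self.width >= self.height > 0):
            raise GeometryError("rect requires width >= height > 0")

    def area(self) -> float:
        return float(self.width * self.height)

    def corners(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        u = np.array([c, s]) * (self.width / 2)
        v = np.array([-s, c]) * (self.height / 2)
        return self.center + np.array([u + v, -u + v, -u - v, u - v])

    def bbox_radius(self) -> float:
        return float(np.linalg.norm(self.center) + np.hypot(self.width, self.height) / 2)


@dataclass(frozen=True)
class Polygon:
    """Convex polygon proxy (lock hulls), counter-clockwise."""

    vertices: np.ndarray
    collision_class: str = "lock"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if len(v) < 3:
            raise GeometryError("polygon needs >= 3 vertices")
        object.__setattr__(self, "vertices", v)

    def area(self) -> float:
        return abs(_shoelace(self.vertices))

    def bbox_radius(self) -> float:
        return float(np.max(np.linalg.norm(self.vertices, axis=1)))


ColliderShape = Circle | Rect | Polygon


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area (positive = counter-clockwise in a Y-up frame)."""
    return _shoelace(np.asarray(vertices, dtype=float))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_contour(alpha_mask: np.ndarray, nm_per_pixel: float) -> Contour:
    """Trace the outer boundary of the largest opaque component of a mask.

    ``alpha_mask`` is any 2D array; pixels > 0.5 (after normalising 8-bit
    values) are opaque. The boundary is returned in nm, Y-up, centered on its
    own centroid, counter-clockwise. Holes and smaller components are ignored.
    """
    if nm_per_pixel <= 0:
        raise GeometryError("nm_per_pixel must be > 0")
    mask = np.asarray(alpha_mask)
    if mask.dtype == np.uint8:
        mask = mask / 255.0
    binary = mask > 0.5
    if not binary.any():
        raise GeometryError("no opaque region in mask")

    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == np.argmax(counts)

    padded = np.pad(largest.astype(float), 1)
    traces = measure.find_contours(padded, 0.5)
    if not traces:  # pragma: no cover - largest component always traceable
        raise GeometryError("no opaque region in mask")
    trace = max(traces, key=len)
    # (row, col) -> (x, y) with Y-up; padding offset removed
    xy = np.column_stack([trace[:, 1] - 1.0, -(trace[:, 0] - 1.0)]) * nm_per_pixel
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    # drop near-duplicate consecutive points
    keep = np.ones(len(xy), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(xy, axis=0), axis=1) > _EPS
    xy = xy[keep]
    xy = xy - xy.mean(axis=0)
    if _shoelace(xy) < 0:
        xy = xy[::-1]
    return Contour(xy, closed=True)


def eigen_frame(contour: Contour | np.ndarray) -> EigenFrame:
    """Eigen-decompose the 2x2 covariance of contour vertices.

    Degenerate (collinear) input clamps the minor eigenvalue to a tiny
    positive value and warns rather than failing.
    """
    v = contour.vertices if isinstance(contour, Contour) else np.asarray(contour, float)
    center = v.mean(axis=0)
    d = v - center
    cov = d.T @ d / len(v)
    lam, vec = np.linalg.eigh(cov)       # ascending
    lam = lam[::-1].copy()
    vec = vec[:, ::-1]
    if lam[1] <= _EPS:
        warnings.warn("degenerate contour: minor eigenvalue clamped", stacklevel=2)
        lam[1] = _EPS
    major = vec[:, 0]
    if major[0] < -_EPS or (abs(major[0]) <= _EPS and major[1] < 0):
        major = -major
    minor = np.array([-major[1], major[0]])   # right-handed completion
    return EigenFrame(center=center, axes=np.array([major, minor]), eigenvalues=lam)


def select_collider(
    frame: EigenFrame,
    contour: Contour,
    threshold: float = defaults.EIGEN_THRESHOLD,
    mode: str = "ratio",
    collision_class: str = "protein",
) -> ColliderShape:
    """Choose a circle or oriented-rectangle proxy for a contour.

    The decision compares the eigenvalues (``mode="ratio"``: lam1/lam2;
    ``mode="difference"``: lam1-lam2) against ``threshold``; below threshold a
    circle is used, otherwise a rectangle. Sizes come from the projected
    contour extents along the eigenvectors.
    """
    if mode == "ratio":
        stat = frame.eigenvalues[0] / frame.eigenvalues[1]
    elif mode == "difference":
        stat = frame.eigenvalues[0] - frame.eigenvalues[1]
    else:
        raise GeometryError(f"unknown selection mode {mode!r}")
    d = contour.vertices - frame.center
    proj_major = d @ frame.axes[0]
    if stat < threshold:
        radius = float(np.max(np.abs(proj_major)))
        return Circle(center=frame.center, radius=radius, collision_class=collision_class)
    proj_minor = d @ frame.axes[1]
    width = float(proj_major.max() - proj_major.min())
    height = float(proj_minor.max() - proj_minor.min())
    angle = frame.angle
    if height > width:  # pragma: no cover - eigen ordering prevents this
        width, height = height, width
        angle += np.pi / 2
    return Rect(center=frame.center, width=width, height=max(height, _EPS),
                angle=angle, collision_class=collision_class)


def graham_hull(points: np.ndarray, collision_class: str = "lock") -> Polygon:
    """Graham-scan convex hull: counter-clockwise, minimal vertex set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise GeometryError("convex hull needs >= 3 points")
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        raise GeometryError("convex hull needs >= 3 distinct points")

    # pivot: lowest y, then lowest x
    pivot_idx = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    pivot = pts[pivot_idx]
    rest = np.delete(pts, pivot_idx, axis=0)
    rel = rest - pivot
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    dist = np.linalg.norm(rel, axis=1)
    order = np.lexsort((dist, ang))
    sorted_pts = rest[order]

    hull = [pivot]
    for p in sorted_pts:
        while len(hull) >= 2:
            cross = _cross2(hull[-1] - hull[-2], p - hull[-2])
            if cross > _EPS:
                break
            hull.pop()  # right turn or collinear: drop interior vertex
        hull.append(p)
    if len(hull) < 3:
        raise GeometryError("degenerate hull: points are collinear")
    return Polygon(np.array(hull), collision_class=collision_class)


def mean_shift_clusters(
    points: np.ndarray,
    bandwidth: float = defaults.LOCK_BANDWIDTH_NM,
    tol: float = defaults.MEANSHIFT_TOL_NM,
    max_iter: int = defaults.MEANSHIFT_MAX_ITER,
) -> list[list[int]]:
    """Flat-kernel mean shift over 2D points.

    Each point climbs to the mean of all points strictly within ``bandwidth``
    of its current position, until the shift drops below ``tol`` or
    ``max_iter`` iterations. Converged modes within bandwidth/2 of each other
    are merged; every point belongs to exactly one cluster. Returns clusters
    as lists of point indices, ordered by first member.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        raise GeometryError("mean shift needs >= 1 point")
    if bandwidth <= 0:
        raise GeometryError("bandwidth must be > 0")

    modes = pts.copy()
    for _ in range(max_iter):
        dist = np.linalg.norm(modes[:, None, :] - pts[None, :, :], axis=2)
        within = dist < bandwidth
        # every point is within bandwidth of itself, so counts >= 1
        counts = within.sum(axis=1)
        new_modes = (within[:, :, None] * pts[None, :, :]).sum(axis=1) / counts[:, None]
        shift = np.linalg.norm(new_modes - modes, axis=1).max()
        modes = new_modes
        if shift < tol:
            break

    clusters: list[list[int]] = []
    centers: list[np.ndarray] = []
    for i, m in enumerate(modes):
        for ci, c in enumerate(centers):
            if np.linalg.norm(m - c) < bandwidth / 2:
                clusters[ci].append(i)
                break
        else:
            centers.append(m)
            clusters.append([i])
    return clusters


def orientation(polygon: Contour) -> str:
    """Winding of a closed polygon: "clockwise" or "counter-clockwise" (Y-up)."""
    a = _shoelace(polygon.vertices)
    if abs(a) < _EPS:
        raise GeometryError("degenerate polygon: zero area")
    return "counter-clockwise" if a > 0 else "clockwise"


def _point_in_triangle(p, a, b, c) -> bool:
    d1 = _cross2(b - a, p - a)
    d2 = _cross2(c - b, p - b)
    d3 = _cross2(a - c, p - c)
    return (d1 >= -_EPS) and (d2 >= -_EPS) and (d3 >= -_EPS)


def triangulate(polygon: Contour) -> list[np.ndarray]:
    """Ear-clipping triangulation of a simple closed polygon.

    Returns n-2 coordinate triangles whose union is the polygon; total area is
    conserved to machine precision. Self-intersecting input fails.
    """
    if not polygon.closed:
        raise GeometryError("triangulation requires a closed polygon")
    from shapely.geometry import Polygon as _ShapelyPolygon

    if not _ShapelyPolygon(polygon.vertices).is_valid:
        raise GeometryError("triangulation failed (self-intersecting polygon?)")
    verts = polygon.vertices
    if _shoelace(verts) < 0:
        verts = verts[::-1]
    n = len(verts)
    idx = list(range(n))
    triangles: list[np.ndarray] = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 2 * n * n:
            raise GeometryError("triangulation failed (self-intersecting polygon?)")
        ear_found = False
        for k in range(len(idx)):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % len(idx)]
            a, b, c = verts[i0], verts[i1], verts[i2]
            if _cross2(b - a, c - a) <= _EPS:
                continue  # reflex or degenerate corner
            others = (verts[j] for j in idx if j not in (i0, i1, i2))
            if any(_point_in_triangle(p, a, b, c) for p in others):
                continue
            triangles.append(np.array([a, b, c]))
            idx.pop(k)
            ear_found = True
            break
        if not ear_found:
            raise GeometryError("triangulation failed (self-intersecting polygon?)")
    triangles.append(verts[idx])
    return triangles
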