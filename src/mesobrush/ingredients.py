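"""Ingredient factory.

Builds paintable molecular species from atomic structures or transparent
images: longest-axis viewpoint selection, coarse disc-sprite rendering,
membrane-binding contour partition, fiber parameterization and collider
assembly. Structures arrive in Angstrom and are converted to nm here; all
downstream coordinates are nm in the sprite-centered, Y-up frame.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

from . import defaults
from .geometry import (
    Circle,
    ColliderShape,
    Contour,
    GeometryError,
    Rect,
    eigen_frame,
    extract_contour,
    select_collider,
)

__all__ = [
    "StructureModel",
    "Sprite",
    "MembraneBinding",
    "FiberSpec",
    "Ingredient",
    "IngredientError",
    "longest_axis",
    "render_sprite",
    "partition_contour",
    "make_soluble",
    "make_membrane_bound",
    "make_fiber_subunit",
    "ingredient_from_image",
    "ELEMENT_COLORS",
]

_EPS = 1e-12


class IngredientError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Atomic structure: elements, 3D coordinates (Angstrom), radii (Angstrom)."""

    elements: list[str]
    coords: np.ndarray          # (n, 3) Angstrom
    radii: np.ndarray           # (n,) Angstrom
    chains: list[str] | None = None
    assembly_id: str = "1"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.coords) == 0:
            raise IngredientError("structure has no atoms")
        if np.any(self.radii <= 0):
            raise IngredientError("atom radii must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class Sprite:
    """Pre-rendered RGBA molecule image with scale and derived contour."""

    image: np.ndarray           # (h, w, 4) uint8
    nm_per_pixel: float
    contour: Contour
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 4:
            raise IngredientError("sprite image must be RGBA")
        if not (self.image[:, :, 3] > 127).any():
            raise IngredientError("sprite has no opaque pixel")


@dataclass(frozen=True)
class MembraneBinding:
    """Membrane interaction parameters, nm / rad (Y-up sprite frame).

    ``surface_offset`` is the Y displacement of the protein center above the
    membrane center; the membrane centerline sits at y = -surface_offset in
    the sprite frame.
    """

    thickness: float
    surface_offset: float = 0.0
    padding: float = 0.0
    rotation: float = 0.0

    def __post_init__(self):
        if self.thickness <= 0:
            raise IngredientError("membrane thickness must be > 0")
        if self.padding < 0:
            raise IngredientError("padding must be >= 0")


@dataclass(frozen=True)
class FiberSpec:
    """Fiber subunit parameters: spacing (nm), twist (rad), persistence springs."""

    spacing: float
    subunit_rotation: float = 0.0
    n_springs: int = defaults.SPRING_PRESETS["user"]
    angle_limit: float | None = None
    preset: str = "user"

    def __post_init__(self):
        if self.spacing <= 0:
            raise IngredientError("fiber spacing must be > 0")
        if self.n_springs < 0:
            raise IngredientError("n_springs must be >= 0")

    @classmethod
    def preset_for(cls, name: str, spacing: float, **kw) -> "FiberSpec":
        """Built-in stiffness presets: dna=10 springs, rna=0, membrane=3, user=3."""
        name = name.lower()
        if name not in defaults.SPRING_PRESETS:
            raise IngredientError(f"unknown fiber preset {name!r}")
        return cls(spacing=spacing, n_springs=defaults.SPRING_PRESETS[name],
                   preset=name, **kw)


@dataclass
class MembraneColliders:
    exterior_box: Rect | None
    interior_box: Rect | None
    wheels: list[Circle]


@dataclass
class Ingredient:
    """One paintable molecular species."""

    name: str
    kind: str                   # soluble | membrane_bound | fiber
    sprite: Sprite
    main_collider: ColliderShape
    membrane_colliders: MembraneColliders | None = None
    end_circles: tuple[Circle, Circle] | None = None
    binding: MembraneBinding | None = None
    fiber: FiberSpec | None = None
    color: tuple[float, float, float] = (0.7, 0.7, 0.7)
    compartment: str = "cytoplasm"

    def __post_init__(self):
        if self.kind not in ("soluble", "membrane_bound", "fiber"):
            raise IngredientError(f"unknown ingredient kind {self.kind!r}")
        if (self.kind == "membrane_bound") != (self.membrane_colliders is not None):
            raise IngredientError("membrane colliders present iff kind=membrane_bound")
        if (self.kind == "fiber") != (self.fiber is not None):
            raise IngredientError("fiber spec present iff kind=fiber")

    def all_colliders(self) -> list[ColliderShape]:
        out: list[ColliderShape] = [self.main_collider]
        if self.membrane_colliders is not None:
            mc = self.membrane_colliders
            out.extend(b for b in (mc.exterior_box, mc.interior_box) if b is not None)
            out.extend(mc.wheels)
        if self.end_circles is not None:
            out.extend(self.end_circles)
        return out


class ContourPartition(NamedTuple):
    exterior: np.ndarray        # index arrays into contour.vertices
    intramembrane: np.ndarray
    interior: np.ndarray


# ---------------------------------------------------------------------------
# element data for rendering
# ---------------------------------------------------------------------------

ELEMENT_COLORS = {
    "C": (200, 200, 200), "N": (143, 170, 220), "O": (230, 130, 130),
    "S": (230, 220, 120), "P": (235, 175, 110), "H": (240, 240, 240),
    "FE": (200, 130, 70), "MG": (130, 220, 130), "ZN": (160, 160, 180),
}
_DEFAULT_COLOR = (185, 170, 200)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def longest_axis(structure: StructureModel) -> np.ndarray:
    """Principal axis of the atomic position covariance, as a unit vector.

    Deterministic sign: non-negative Z component, ties broken toward +Y then
    +X. Near-isotropic structures are accepted with a warning.
    """
    if structure.n_atoms < 2:
        raise IngredientError("longest axis undefined for a single atom")
    d = structure.coords - structure.coords.mean(axis=0)
    cov = d.T @ d / len(d)
    lam, vec = np.linalg.eigh(cov)
    axis = vec[:, -1]
    if lam[-1] <= _EPS:
        raise IngredientError("all atoms coincide; no axis")
    if lam[1] / max(lam[-1], _EPS) > 0.9:
        warnings.warn("near-degenerate (isotropic) structure; axis arbitrary",
                      stacklevel=2)
    for k in (2, 1, 0):
        if abs(axis[k]) > 1e-9:
            if axis[k] < 0:
                axis = -axis
            break
    return axis


def _rotation_to_y(axis: np.ndarray) -> Rotation:
    target = np.array([0.0, 1.0, 0.0])
    rot, _ = Rotation.align_vectors(target[None, :], axis[None, :])
    return rot


def render_sprite(
    structure: StructureModel,
    nm_per_pixel: float,
    orient: str | Rotation = "auto",
    coarsen: float = defaults.COARSEN_FACTOR,
) -> Sprite:
    """Render a coarse flat-shaded disc sprite of a structure.

    The longest axis is aligned to image Y (``orient="auto"``) and atoms are
    projected along Z, drawn back-to-front as filled discs with a darker
    outline on a fully transparent background. The contour of the result is
    extracted at the stated scale.
    """
    if nm_per_pixel <= 0:
        raise IngredientError("nm_per_pixel must be > 0")
    if isinstance(orient, Rotation):
        rot = orient
    elif orient == "auto":
        rot = _rotation_to_y(longest_axis(structure)) if structure.n_atoms > 1 \
            else Rotation.identity()
    elif orient == "none":
        rot = Rotation.identity()
    else:
        raise IngredientError(f"unknown orient {orient!r}")

    xyz_nm = rot.apply(structure.coords - structure.coords.mean(axis=0)) / 10.0
    radii_nm = structure.radii * coarsen / 10.0

    lo = (xyz_nm[:, :2] - radii_nm[:, None]).min(axis=0)
    hi = (xyz_nm[:, :2] + radii_nm[:, None]).max(axis=0)
    size_px = np.ceil((hi - lo) / nm_per_pixel).astype(int) + 3
    w, h = int(size_px[0]), int(size_px[1])
    if min(w, h) < 3 or radii_nm.max() < nm_per_pixel / 2:
        raise IngredientError("scale too coarse: sprite smaller than 3 px")

    img = np.zeros((h, w, 4), dtype=np.uint8)
    cx = (lo[0] + hi[0]) / 2
    cy = (lo[1] + hi[1]) / 2
    yy, xx = np.mgrid[0:h, 0:w]
    # pixel-center world coordinates (Y-up: row 0 is the top)
    px = (xx - (w - 1) / 2) * nm_per_pixel + cx
    py = ((h - 1) / 2 - yy) * nm_per_pixel + cy

    order = np.argsort(xyz_nm[:, 2], kind="stable")   # far (small z) first
    outline_nm = max(nm_per_pixel, 0.05)
    for i in order:
        x0, y0 = xyz_nm[i, 0], xyz_nm[i, 1]
        r = radii_nm[i]
        d2 = (px - x0) ** 2 + (py - y0) ** 2
        fill = np.array(ELEMENT_COLORS.get(structure.elements[i].upper(),
                                           _DEFAULT_COLOR))
        edge = (fill * defaults.OUTLINE_SHADE).astype(np.uint8)
        disc = d2 <= r * r
        core = d2 <= max(r - outline_nm, 0.0) ** 2
        img[disc, :3] = edge
        img[core, :3] = fill
        img[disc, 3] = 255

    contour = extract_contour(img[:, :, 3], nm_per_pixel)
    return Sprite(image=img, nm_per_pixel=nm_per_pixel, contour=contour)


def partition_contour(contour: Contour, binding: MembraneBinding) -> ContourPartition:
    """Split contour vertices into exterior / intramembrane / interior sets.

    The membrane centerline is y = -surface_offset in the sprite frame;
    vertices more than thickness/2 + padding above it are exterior, more than
    that below are interior, the rest intramembrane.
    """
    y = contour.vertices[:, 1]
    line = -binding.surface_offset
    half = binding.thickness / 2 + binding.padding
    exterior = np.where(y > line + half)[0]
    interior = np.where(y < line - half)[0]
    intra = np.where((y >= line - half) & (y <= line + half))[0]
    if len(exterior) == 0 and len(interior) == 0:
        warnings.warn("all contour points intramembrane: no anchor boxes, "
                      "wheels only", stacklevel=2)
    return ContourPartition(exterior=exterior, intramembrane=intra, interior=interior)


def _forced_rect(points: np.ndarray, collision_class: str) -> Rect | None:
    """Best-fit oriented rectangle over a vertex subset (None if < 3 points)."""
    if len(points) < 3:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear subsets are fine here
        frame = eigen_frame(points)
    d = points - frame.center
    pj = d @ frame.axes[0]
    pn = d @ frame.axes[1]
    width = float(pj.max() - pj.min())
    height = float(pn.max() - pn.min())
    angle = frame.angle
    width = max(width, 0.1)
    height = max(height, 0.1)
    if height > width:
        width, height = height, width
        angle += np.pi / 2
    return Rect(center=frame.center, width=width, height=height, angle=angle,
                collision_class=collision_class)


def make_soluble(sprite: Sprite, name: str = "soluble",
                 color=(0.7, 0.7, 0.7), compartment="cytoplasm",
                 threshold: float = defaults.EIGEN_THRESHOLD) -> Ingredient:
    """Soluble species: a single main collider chosen from the contour."""
    frame = eigen_frame(sprite.contour)
    main = select_collider(frame, sprite.contour, threshold=threshold,
                           collision_class="protein")
    return Ingredient(name=name, kind="soluble", sprite=sprite,
                      main_collider=main, color=color, compartment=compartment)


def make_membrane_bound(sprite: Sprite, binding: MembraneBinding,
                        name: str = "membrane_protein",
                        color=(0.7, 0.7, 0.7), compartment="membrane",
                        threshold: float = defaults.EIGEN_THRESHOLD) -> Ingredient:
    """Membrane-bound species: main collider plus the rail/wheel collider group.

    The main collider (protein class) comes from the full contour; exterior
    and interior boxes are rectangles fitted to the corresponding partition
    subsets; four wheel circles of radius thickness/2 straddle the membrane
    line just outside the main collider's width.
    """
    contour = sprite.contour
    frame = eigen_frame(contour)
    main = select_collider(frame, contour, threshold=threshold,
                           collision_class="protein")
    part = partition_contour(contour, binding)
    verts = contour.vertices
    ext_box = _forced_rect(verts[part.exterior], "membrane")
    int_box = _forced_rect(verts[part.interior], "membrane")

    if isinstance(main, Circle):
        half_w = main.radius
    else:
        half_w = main.width / 2
    wheel_r = binding.thickness / 2
    wx = half_w + wheel_r
    line = -binding.surface_offset
    wy = binding.thickness / 2 + binding.padding
    wheels = [
        Circle(center=np.array([sx * wx, line + sy * wy]), radius=wheel_r,
               collision_class="membrane")
        for sx in (-1.0, 1.0) for sy in (1.0, -1.0)
    ]
    mc = MembraneColliders(exterior_box=ext_box, interior_box=int_box, wheels=wheels)
    return Ingredient(name=name, kind="membrane_bound", sprite=sprite,
                      main_collider=main, membrane_colliders=mc, binding=binding,
                      color=color, compartment=compartment)


def make_fiber_subunit(sprite: Sprite, spec: FiberSpec, name: str = "fiber",
                       color=(0.7, 0.7, 0.7), compartment="cytoplasm") -> Ingredient:
    """Fiber subunit: rectangular main collider plus two hinge-anchor end circles.

    The sprite is expected horizontal (major axis along X). End circles sit at
    (+-spacing/2, 0) with radius equal to the minor half-extent; they anchor
    the hinge joints and fill the inter-subunit gap at acute angles, and are
    excluded from collisions with the neighboring subunits' colliders.
    """
    contour = sprite.contour
    frame = eigen_frame(contour)
    d = contour.vertices - frame.center
    width = float((d @ frame.axes[0]).max() - (d @ frame.axes[0]).min())
    height = float((d @ frame.axes[1]).max() - (d @ frame.axes[1]).min())
    if height > width:
        width, height = height, width
    main = Rect(center=frame.center, width=max(width, height),
                height=max(height, 1e-6), angle=0.0, collision_class="fiber")
    if spec.spacing > 2 * width:
        warnings.warn("fiber spacing exceeds twice the subunit width: gappy fiber",
                      stacklevel=2)
    r = height / 2
    circles = (
        Circle(center=np.array([-spec.spacing / 2, 0.0]), radius=r,
               collision_class="fiber"),
        Circle(center=np.array([spec.spacing / 2, 0.0]), radius=r,
               collision_class="fiber"),
    )
    return Ingredient(name=name, kind="fiber", sprite=sprite, main_collider=main,
                      end_circles=circles, fiber=spec, color=color,
                      compartment=compartment)


def ingredient_from_image(image: np.ndarray, nm_per_pixel: float, kind: str,
                          name: str = "custom",
                          binding: MembraneBinding | None = None,
                          fiber: FiberSpec | None = None,
                          color=(0.7, 0.7, 0.7),
                          compartment: str = "cytoplasm") -> Ingredient:
    """Build an ingredient from a transparent RGBA image.

    Routes through contour extraction then the kind-specific factory. Images
    without an alpha channel (or fully opaque ones) are rejected.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 4:
        raise IngredientError("image must have a transparency (alpha) channel")
    if (img[:, :, 3] > 127).all():
        raise IngredientError("image has no transparent background")
    contour = extract_contour(img[:, :, 3], nm_per_pixel)
    sprite = Sprite(image=img.astype(np.uint8), nm_per_pixel=nm_per_pixel,
                    contour=contour)
    if kind == "soluble":
        return make_soluble(sprite, name=name, color=color, compartment=compartment)
    if kind == "membrane_bound":
        if binding is None:
            raise IngredientError("membrane_bound ingredient needs binding params")
        return make_membrane_bound(sprite, binding, name=name, color=color,
                                   compartment=compartment)
    if kind == "fiber":
        if fiber is None:
            raise IngredientError("fiber ingredient needs a FiberSpec")
        return make_fiber_subunit(sprite, fiber, name=name, color=color,
                                  compartment=compartment)
    raise IngredientError(f"unknown ingredient kind {kind!r}")
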