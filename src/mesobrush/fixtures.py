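"""Synthetic fixture generators.

Deterministic contours, masks, toy structures, stroke paths, a miniature
multi-compartment recipe and a demo scene, so every module is testable with
no external data or network.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import Contour
from .ingredients import (
    FiberSpec,
    Ingredient,
    MembraneBinding,
    StructureModel,
    ingredient_from_image,
)

__all__ = [
    "ellipse_contour", "blob_contour", "disc_mask", "bar_mask", "blob_mask",
    "dumbbell_mask", "sprite_image", "rod_structure", "helix_structure",
    "globule_structure", "circle_stroke", "arc_stroke", "s_curve_stroke",
    "demo_ingredients", "demo_recipe_data", "write_demo_recipe", "generate",
]


# ---------------------------------------------------------------------------
# contours and masks
# ---------------------------------------------------------------------------

def ellipse_contour(a: float, b: float, n: int = 256, angle: float = 0.0,
                    center=(0.0, 0.0)) -> Contour:
    """Uniform-angle polygonal ellipse; vertex covariance = diag(a^2, b^2)/2."""
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    c, s = np.cos(angle), np.sin(angle)
    pts = pts @ np.array([[c, s], [-s, c]])
    return Contour(pts + np.asarray(center, dtype=float))


def blob_contour(seed: int, n: int = 128, mean_radius: float = 4.0,
                 roughness: float = 0.25) -> Contour:
    """Random star-shaped (hence simple) polygon with smooth radius noise."""
    rng = np.random.default_rng(seed)
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = np.full(n, mean_radius)
    for k in range(2, 6):
        r += mean_radius * roughness / k * (
            rng.normal() * np.cos(k * th) + rng.normal() * np.sin(k * th))
    r = np.clip(r, 0.3 * mean_radius, None)
    return Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def disc_mask(radius_px: int, pad: int = 1) -> np.ndarray:
    size = 2 * radius_px + 1 + 2 * pad
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    return (((yy - c) ** 2 + (xx - c) ** 2) <= radius_px**2).astype(float)


def bar_mask(width_px: int, height_px: int, pad: int = 1) -> np.ndarray:
    mask = np.zeros((height_px + 2 * pad, width_px + 2 * pad))
    mask[pad:pad + height_px, pad:pad + width_px] = 1.0
    return mask


def blob_mask(seed: int, size: int = 48) -> np.ndarray:
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    th = np.arctan2(yy - c, xx - c)
    r = np.hypot(yy - c, xx - c)
    radius = size * 0.3 * np.ones_like(th)
    for k in range(2, 5):
        radius += size * 0.05 / k * (rng.normal() * np.cos(k * th)
                                     + rng.normal() * np.sin(k * th))
    return (r <= radius).astype(float)


def dumbbell_mask(lobe_px: int = 8, neck_px: int = 4,
                  neck_len_px: int = 10) -> np.ndarray:
    """Vertical dumbbell: two lobes joined by a thin neck (Y-up symmetric)."""
    h = 4 * lobe_px + neck_len_px + 4
    w = 2 * lobe_px + 4
    mask = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    cx = w // 2
    top = lobe_px + 2
    bot = h - lobe_px - 3
    mask[((yy - top) ** 2 + (xx - cx) ** 2) <= lobe_px**2] = 1
    mask[((yy - bot) ** 2 + (xx - cx) ** 2) <= lobe_px**2] = 1
    mask[top:bot, cx - neck_px // 2:cx + neck_px // 2 + 1] = 1
    return mask


def sprite_image(mask: np.ndarray, color=(180, 180, 210)) -> np.ndarray:
    """RGBA image from a binary mask (transparent background)."""
    h, w = mask.shape
    img = np.zeros((h, w, 4), dtype=np.uint8)
    on = mask > 0.5
    img[on, 0], img[on, 1], img[on, 2] = color
    img[on, 3] = 255
    return img


# ---------------------------------------------------------------------------
# toy structures (pseudo-atoms, Angstrom)
# ---------------------------------------------------------------------------

def rod_structure(n: int = 10, length: float = 30.0,
                  axis=(1.0, 0.0, 0.0)) -> StructureModel:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.linspace(-length / 2, length / 2, n)
    return StructureModel(elements=["C"] * n, coords=np.outer(t, axis),
                          radii=np.full(n, 1.7))


def helix_structure(n: int = 40, rise: float = 1.5, radius: float = 2.3,
                    twist_deg: float = 100.0, axis="z") -> StructureModel:
    """Idealized alpha-helix-like pseudo-atom spiral along +Z."""
    th = np.radians(twist_deg) * np.arange(n)
    coords = np.column_stack([radius * np.cos(th), radius * np.sin(th),
                              rise * np.arange(n)])
    coords -= coords.mean(axis=0)
    return StructureModel(elements=["C"] * n, coords=coords,
                          radii=np.full(n, 1.9))


def globule_structure(seed: int = 0, n: int = 60,
                      radius: float = 12.0) -> StructureModel:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = radius * rng.uniform(0.3, 1.0, size=n) ** (1 / 3)
    return StructureModel(elements=["C"] * n, coords=v * r[:, None],
                          radii=np.full(n, 1.8))


# ---------------------------------------------------------------------------
# strokes
# ---------------------------------------------------------------------------

def circle_stroke(radius: float, n: int = 200, center=(0.0, 0.0),
                  clockwise: bool = False) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n)
    if clockwise:
        th = th[::-1]
    return np.column_stack([radius * np.cos(th) + center[0],
                            radius * np.sin(th) + center[1]])


def arc_stroke(radius: float, span_rad: float = np.pi, n: int = 100,
               center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0.0, span_rad, n)
    return np.column_stack([radius * np.cos(th) + center[0],
                            radius * np.sin(th) + center[1]])


def s_curve_stroke(length: float = 120.0, amplitude: float = 20.0,
                   n: int = 200) -> np.ndarray:
    x = np.linspace(-length / 2, length / 2, n)
    y = amplitude * np.sin(2 * np.pi * x / length)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# demo recipe / scene
# ---------------------------------------------------------------------------

def demo_ingredients(seed: int = 0) -> dict[str, Ingredient]:
    """Miniature palette: soluble blob, membrane-bound dumbbell, DNA-like
    fiber and a membrane subunit."""
    blob = ingredient_from_image(
        sprite_image(blob_mask(seed), color=(120, 170, 220)), 0.25, "soluble",
        name="blob", color=(0.5, 0.7, 0.9), compartment="cytoplasm")
    dumb = ingredient_from_image(
        sprite_image(dumbbell_mask(), color=(220, 160, 120)), 0.25,
        "membrane_bound", name="receptor",
        binding=MembraneBinding(thickness=4.0, surface_offset=2.0, padding=0.5),
        color=(0.9, 0.6, 0.4), compartment="membrane")
    dna = ingredient_from_image(
        sprite_image(bar_mask(40, 8), color=(170, 140, 220)), 0.25, "fiber",
        name="dna", fiber=FiberSpec.preset_for("dna", spacing=10.0),
        color=(0.6, 0.5, 0.9), compartment="nucleoid")
    membrane = ingredient_from_image(
        sprite_image(bar_mask(40, 16), color=(150, 210, 160)), 0.25, "fiber",
        name="lipid", fiber=FiberSpec.preset_for("membrane", spacing=10.0),
        color=(0.55, 0.8, 0.6), compartment="membrane")
    return {i.name: i for i in (blob, dumb, dna, membrane)}


def demo_recipe_data() -> dict:
    return {
        "format_version": 1,
        "name": "demo",
        "compartments": [
            {"name": "cytoplasm", "ingredients": [
                {"name": "blob", "kind": "soluble", "sprite": "sprites/blob.png",
                 "nm_per_pixel": 0.25, "color": [0.5, 0.7, 0.9]}]},
            {"name": "membrane", "ingredients": [
                {"name": "receptor", "kind": "membrane_bound",
                 "sprite": "sprites/receptor.png", "nm_per_pixel": 0.25,
                 "color": [0.9, 0.6, 0.4],
                 "binding": {"thickness": 4.0, "surface_offset": 2.0,
                             "padding": 0.5}},
                {"name": "lipid", "kind": "fiber",
                 "sprite": "sprites/lipid.png", "nm_per_pixel": 0.25,
                 "color": [0.55, 0.8, 0.6],
                 "fiber": {"spacing": 10.0, "preset": "membrane"}}]},
            {"name": "nucleoid", "ingredients": [
                {"name": "dna", "kind": "fiber", "sprite": "sprites/dna.png",
                 "nm_per_pixel": 0.25, "color": [0.6, 0.5, 0.9],
                 "fiber": {"spacing": 10.0, "preset": "dna"}}]},
        ],
    }


def write_demo_recipe(outdir: str | Path, seed: int = 0):
    """Write the demo recipe JSON + sprite PNGs; returns the recipe path."""
    from .io import Recipe, save_recipe, save_sprite_png

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ings = demo_ingredients(seed)
    data = demo_recipe_data()
    for comp in data["compartments"]:
        for entry in comp["ingredients"]:
            save_sprite_png(ings[entry["name"]].sprite.image,
                            outdir / entry["sprite"])
    recipe = Recipe(name="demo", data=data, ingredients=ings, base_dir=outdir)
    save_recipe(recipe, outdir / "recipe.json")
    return outdir / "recipe.json"


def demo_scene(seed: int = 0, n_bodies: int = 20):
    """A ~20-body scene exercising paint, fibers and a closed vesicle."""
    from .scene import Scene
    from .strokes import StrokePath
    from .physics import WorldConfig

    scene = Scene(canvas=(400.0, 400.0), config=WorldConfig(rng_seed=seed))
    for ing in demo_ingredients(seed).values():
        scene.add_ingredient(ing)
    rng = np.random.default_rng(seed)
    scene.draw_membrane("lipid", StrokePath(circle_stroke(60.0, clockwise=True),
                                            layer=0))
    for _ in range(max(6, n_bodies - len(scene.instances))):
        pos = rng.uniform(-180, 180, size=2)
        scene.paint("blob", pos, layer=int(rng.integers(0, 3)), settle=False)
    scene.settle(max_steps=50)
    return scene


# ---------------------------------------------------------------------------
# file-producing dispatcher (CLI entry)
# ---------------------------------------------------------------------------

def generate(kind: str, params: dict, seed: int, outdir: str | Path) -> list[Path]:
    """Write deterministic synthetic assets of the given kind; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "contour":
        a = float(params.get("a", 4.0))
        b = float(params.get("b", 1.0))
        c = ellipse_contour(a, b, int(params.get("n", 256)))
        p = outdir / "contour.json"
        p.write_text(json.dumps({"vertices": c.vertices.tolist(),
                                 "closed": True}))
        written.append(p)
    elif kind == "structure":
        shape = params.get("shape", "rod")
        maker = {"rod": rod_structure, "helix": helix_structure,
                 "globule": lambda: globule_structure(seed)}[shape]
        s = maker()
        p = outdir / f"{shape}.pdb"
        _write_pdb(s, p)
        written.append(p)
    elif kind == "stroke":
        shape = params.get("shape", "circle")
        pts = {"circle": lambda: circle_stroke(float(params.get("radius", 50.0)),
                                               clockwise=True),
               "arc": lambda: arc_stroke(float(params.get("radius", 50.0))),
               "s": s_curve_stroke}[shape]()
        p = outdir / f"stroke_{shape}.json"
        p.write_text(json.dumps({"points": pts.tolist()}))
        written.append(p)
    elif kind == "recipe":
        written.append(write_demo_recipe(outdir, seed))
    elif kind == "scene":
        from .io import save_scene, Recipe

        recipe_path = write_demo_recipe(outdir, seed)
        scene = demo_scene(seed)
        p = outdir / "scene.txt"
        save_scene(scene, p)
        written.extend([recipe_path, p])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written


def _write_pdb(structure: StructureModel, path: Path) -> None:
    lines = []
    for i, (el, xyz) in enumerate(zip(structure.elements, structure.coords), 1):
        lines.append(
            f"ATOM  {i:5d}  {el:<3s} GLY A{i:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {el:>2s}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
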