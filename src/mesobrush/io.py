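"""Readers and writers: recipe JSON, line-oriented scene text, zip bundles,
PDB/mmCIF structures, sprite PNGs, and deterministic raster rendering.

Formats are documented in docs/formats.md ("format_version": 1). The recipe
reader is permissive: unknown keys are preserved on round trip and a small
alias map accepts legacy field spellings.
"""
from __future__ import annotations

import json
import tempfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from . import defaults
from .ingredients import (
    FiberSpec,
    Ingredient,
    MembraneBinding,
    StructureModel,
    ingredient_from_image,
)
from .physics import PinTo, WorldConfig
from .scene import Scene, SceneError
from . import strokes as _strokes
from .strokes import FiberChain, MembraneChain
from .geometry import Contour, triangulate

__all__ = ["Recipe", "FormatError", "load_recipe", "save_recipe",
           "save_scene", "load_scene", "bundle", "load_bundle",
           "read_structure", "render", "save_sprite_png", "load_image"]

FORMAT_VERSION = 1


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

_BINDING_ALIASES = {"offset": "surface_offset", "surfaceOffset": "surface_offset",
                    "membrane_thickness": "thickness"}
_FIBER_ALIASES = {"repetition": "spacing", "twist": "subunit_rotation",
                  "nSprings": "n_springs"}


@dataclass
class Recipe:
    """Serializable palette: compartments of ingredient definitions.

    ``data`` is the raw (round-trippable) JSON dictionary; ``ingredients``
    holds the constructed Ingredient objects keyed by name.
    """

    name: str
    data: dict
    ingredients: dict[str, Ingredient] = field(default_factory=dict)
    base_dir: Path | None = None

    @property
    def compartments(self) -> list[dict]:
        return self.data.get("compartments", [])


def _normalize(d: dict, aliases: dict) -> dict:
    return {aliases.get(k, k): v for k, v in d.items()}


def _build_ingredient(entry: dict, base_dir: Path, compartment: str) -> Ingredient:
    for key in ("name", "kind", "sprite", "nm_per_pixel"):
        if key not in entry:
            raise FormatError(
                f"recipe ingredient missing key {key!r} "
                f"(at compartments[{compartment!r}].ingredients)")
    sprite_path = base_dir / entry["sprite"]
    if not sprite_path.exists():
        raise FormatError(f"sprite file not found: {sprite_path}")
    img = load_image(sprite_path)
    binding = None
    if entry.get("binding"):
        binding = MembraneBinding(**_normalize(entry["binding"], _BINDING_ALIASES))
    fiber = None
    if entry.get("fiber"):
        f = _normalize(dict(entry["fiber"]), _FIBER_ALIASES)
        preset = f.pop("preset", None)
        if preset:
            fiber = FiberSpec.preset_for(preset, **f)
        else:
            fiber = FiberSpec(**f)
    return ingredient_from_image(
        img, float(entry["nm_per_pixel"]), entry["kind"], name=entry["name"],
        binding=binding, fiber=fiber,
        color=tuple(entry.get("color", (0.7, 0.7, 0.7))),
        compartment=compartment)


def load_recipe(path: str | Path) -> Recipe:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"recipe parse error at {path}: {e}") from e
    if not isinstance(data, dict) or "compartments" not in data:
        raise FormatError(f"recipe schema violation at $.compartments ({path})")
    recipe = Recipe(name=data.get("name", path.stem), data=data,
                    base_dir=path.parent)
    for comp in data["compartments"]:
        if "ingredients" not in comp:
            raise FormatError(
                f"recipe schema violation at $.compartments[].ingredients")
        seen = set()
        for entry in comp["ingredients"]:
            ing = _build_ingredient(entry, path.parent, comp.get("name", ""))
            if ing.name in seen:
                raise FormatError(f"duplicate ingredient name {ing.name!r} "
                                  f"in compartment {comp.get('name')!r}")
            seen.add(ing.name)
            recipe.ingredients[ing.name] = ing
    return recipe


def save_recipe(recipe: Recipe, path: str | Path) -> None:
    """Write the recipe JSON (canonical key order) plus any missing sprites."""
    path = Path(path)
    data = dict(recipe.data)
    data.setdefault("format_version", FORMAT_VERSION)
    data.setdefault("name", recipe.name)
    path.write_text(json.dumps(data, sort_keys=True, indent=2) + "\n")
    for comp in data.get("compartments", []):
        for entry in comp.get("ingredients", []):
            target = path.parent / entry["sprite"]
            if not target.exists() and entry["name"] in recipe.ingredients:
                save_sprite_png(recipe.ingredients[entry["name"]].sprite.image,
                                target)


def save_sprite_png(image: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image, mode="RGBA").save(path)


def load_image(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "RGBA":
        img = img.convert("RGBA")
    return np.array(img)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

def _q(x, nd=3):
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_q(v, nd) for v in x]
    return round(float(x), nd)


def save_scene(scene: Scene, path: str | Path) -> None:
    """Line-oriented JSON scene text: one record per instance/constraint."""
    records: list[dict] = [{
        "record": "scene", "format_version": FORMAT_VERSION,
        "canvas": list(scene.canvas),
        "background_color": list(scene.background_color),
        "rng_seed": scene.world.config.rng_seed,
    }]
    for bg in sorted(scene.backgrounds.values(), key=lambda b: b.id):
        records.append({"record": "background", "image_ref": bg.image_ref,
                        "nm_per_pixel": bg.nm_per_pixel, "opacity": bg.opacity,
                        "rotation": _q(bg.rotation, 6), "z_order": bg.z_order})
    hull_ids = {r.hull_body_id for r in scene.lock_regions.values()}
    for bid in sorted(scene.instances):
        body = scene.world.bodies[bid]
        ing = scene.palette[body.ingredient]
        records.append({
            "record": "instance", "id": bid, "ingredient": body.ingredient,
            "color": list(ing.color), "position": _q(body.position),
            "angle": _q(body.angle, 6), "layer": body.layer,
            "pinned": body.pinned, "group_stamp": body.group_stamp,
        })
    for chain in scene.fiber_chains:
        records.append({"record": "fiber_chain", "ingredient": chain.ingredient,
                        "ids": chain.subunit_ids, "closed": chain.closed,
                        "layers": chain.layer_assignment})
    for chain in scene.membrane_chains:
        records.append({"record": "membrane_chain",
                        "ingredient": chain.ingredient,
                        "ids": chain.segment_ids, "closed": chain.closed,
                        "end_pins": chain.end_pins})
    for c in scene.world.constraints:
        if isinstance(c, PinTo):
            records.append({"record": "pin_to", "a": c.body_a, "b": c.body_b,
                            "local_a": _q(c.local_a), "local_b": _q(c.local_b),
                            "distance": _q(c.distance)})
    for g in sorted(scene.groups.values(), key=lambda g: g.id):
        records.append({"record": "group", "id": g.id,
                        "members": [[n, _q(off), _q(a, 6)]
                                    for n, off, a in g.members],
                        "pin_tos": [[ia, ib, _q(la), _q(lb), _q(d)]
                                    for ia, ib, la, lb, d in g.pin_tos]})
    for r in sorted(scene.lock_regions.values(), key=lambda r: r.id):
        records.append({"record": "lock", "id": r.id,
                        "members": sorted(r.member_ids)})
    Path(path).write_text(
        "\n".join(json.dumps(r, sort_keys=True) for r in records) + "\n")


def load_scene(path: str | Path, recipe: Recipe) -> Scene:
    """Rebuild a scene at exact saved poses (no settling on load)."""
    lines = [json.loads(l) for l in Path(path).read_text().splitlines() if l.strip()]
    header = lines[0]
    if header.get("record") != "scene":
        raise FormatError("scene file must start with a scene record")
    scene = Scene(canvas=header["canvas"],
                  background_color=tuple(header["background_color"]),
                  config=WorldConfig(rng_seed=header.get("rng_seed", 0)))
    for ing in recipe.ingredients.values():
        scene.add_ingredient(ing)

    chains_pending = []
    locks_pending = []
    for rec in lines[1:]:
        kind = rec["record"]
        if kind == "background":
            scene.set_background(rec["image_ref"], rec["nm_per_pixel"],
                                 opacity=rec["opacity"],
                                 rotation=rec["rotation"],
                                 z_order=rec["z_order"])
        elif kind == "instance":
            name = rec["ingredient"]
            if name not in recipe.ingredients:
                raise FormatError(f"scene references unknown ingredient {name!r}")
            body = scene._create_body(scene.palette[name], rec["position"],
                                      angle=rec["angle"], layer=rec["layer"],
                                      body_id=rec["id"])
            body.pinned = bool(rec.get("pinned"))
            body.group_stamp = rec.get("group_stamp")
        elif kind in ("fiber_chain", "membrane_chain"):
            chains_pending.append(rec)
        elif kind == "pin_to":
            scene.world.add_constraint(PinTo(
                body_a=rec["a"], body_b=rec["b"],
                local_a=np.array(rec["local_a"], dtype=float),
                local_b=np.array(rec["local_b"], dtype=float),
                distance=float(rec["distance"])))
        elif kind == "group":
            from .scene import Group
            g = Group(id=rec["id"],
                      members=[(n, np.array(off, dtype=float), float(a))
                               for n, off, a in rec["members"]],
                      pin_tos=[(ia, ib, np.array(la, float), np.array(lb, float),
                                float(d))
                               for ia, ib, la, lb, d in rec["pin_tos"]])
            scene.groups[g.id] = g
            scene._counter = max(scene._counter, g.id)
        elif kind == "lock":
            locks_pending.append(rec)
        else:
            raise FormatError(f"unknown scene record type {kind!r}")

    for rec in chains_pending:
        ids = rec["ids"]
        ing = scene.palette[rec["ingredient"]]
        spec = ing.fiber
        pos = np.array([scene.world.bodies[i].position for i in ids])
        if rec["record"] == "fiber_chain":
            hinges, springs = _strokes._chain_constraints(
                ids, pos, spec.spacing, spec.n_springs, rec["closed"])
            for c in hinges + springs:
                scene.world.add_constraint(c)
            scene.fiber_chains.append(FiberChain(
                ingredient=rec["ingredient"], subunit_ids=ids, hinges=hinges,
                springs=springs, layer_assignment=rec["layers"],
                closed=rec["closed"], wrap_springs=rec["closed"],
                spacing=spec.spacing))
        else:
            n_springs = defaults.SPRING_PRESETS["membrane"]
            hinges, springs = _strokes._chain_constraints(
                ids, pos, spec.spacing, n_springs, rec["closed"])
            for c in hinges + springs:
                scene.world.add_constraint(c)
            chain = MembraneChain(
                ingredient=rec["ingredient"], segment_ids=ids, hinges=hinges,
                springs=springs, closed=rec["closed"], spacing=spec.spacing,
                thickness=min(ing.main_collider.height, ing.main_collider.width)
                if hasattr(ing.main_collider, "height")
                else 2 * ing.main_collider.radius,
                end_pins=list(rec.get("end_pins", [])))
            if chain.closed:
                chain.interior_triangles = triangulate(Contour(pos, closed=True))
                chain.compartment = scene.register_compartment(chain)
            scene.membrane_chains.append(chain)
        for a, b in zip(ids, ids[1:] + ([ids[0]] if rec["closed"] else [])):
            scene.world.bodies[a].no_collide.add(b)
            scene.world.bodies[b].no_collide.add(a)
    for rec in locks_pending:
        region = scene.lock(rec["members"])
        # keep saved region ids stable across round trips
        scene.lock_regions.pop(region.id)
        region.id = rec["id"]
        for bid in rec["members"]:
            scene.world.bodies[bid].lock_id = rec["id"]
        hull = scene.world.bodies.get(region.hull_body_id)
        if hull is not None:
            hull.region_id = rec["id"]
        scene.lock_regions[rec["id"]] = region
        scene._counter = max(scene._counter, rec["id"])
    scene.world.touch()
    scene.update_measurements()
    return scene


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def bundle(scene: Scene, recipe: Recipe, path: str | Path) -> None:
    """Zip archive with the scene text, recipe JSON and every sprite PNG."""
    path = Path(path)
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        save_scene(scene, tmpdir / "scene.txt")
        save_recipe(recipe, tmpdir / "recipe.json")
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.write(tmpdir / "scene.txt", "scene.txt")
            zf.write(tmpdir / "recipe.json", "recipe.json")
            for comp in recipe.data.get("compartments", []):
                for entry in comp.get("ingredients", []):
                    sprite_rel = entry["sprite"]
                    src = tmpdir / sprite_rel
                    if not src.exists():
                        raise FormatError(f"bundle missing sprite {sprite_rel}")
                    zf.write(src, sprite_rel)


def load_bundle(path: str | Path) -> tuple[Scene, Recipe]:
    """Self-contained load: extracts to a scratch dir and loads from there."""
    path = Path(path)
    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as e:
        raise FormatError(f"corrupt zip archive: {path}") from e
    tmpdir = Path(tempfile.mkdtemp(prefix="mesobrush_bundle_"))
    with zf:
        zf.extractall(tmpdir)
    recipe = load_recipe(tmpdir / "recipe.json")
    scene = load_scene(tmpdir / "scene.txt", recipe)
    return scene, recipe


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

_VDW_RADII = {  # Angstrom, standard table; fallback 1.7
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "FE": 2.00, "MG": 1.73,
    "ZN": 1.39, "CA": 2.31, "NA": 2.27, "K": 2.75, "MN": 2.00, "CU": 1.40,
    "SE": 1.90,
}
_CA_ONLY_RADIUS = 3.0   # per-residue fallback for CA traces


def read_structure(path: str | Path, assembly: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (first model only).

    mmCIF files honor ``assembly`` (biological assembly id) when present.
    CA-only traces get a per-residue 3.0 Angstrom radius fallback.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"structure file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif"):
            from biotite.structure.io import pdbx
            cif = pdbx.CIFFile.read(str(path))
            if assembly is not None:
                atoms = pdbx.get_assembly(cif, assembly_id=assembly, model=1)
            else:
                atoms = pdbx.get_structure(cif, model=1)
        elif suffix in (".pdb", ".ent"):
            from biotite.structure.io.pdb import PDBFile
            atoms = PDBFile.read(str(path)).get_structure(model=1)
        else:
            raise FormatError(f"unsupported structure format {suffix!r}")
    except FormatError:
        raise
    except Exception as e:
        raise FormatError(f"unreadable structure file {path}: {e}") from e
    if atoms.array_length() == 0:
        raise FormatError(f"structure file has no atoms: {path}")

    elements = [str(e).upper() for e in atoms.element]
    names = [str(n).strip() for n in atoms.atom_name]
    ca_only = all(n == "CA" for n in names)
    if ca_only:
        radii = np.full(len(elements), _CA_ONLY_RADIUS)
    else:
        radii = np.array([_VDW_RADII.get(e, 1.7) for e in elements])
    return StructureModel(elements=elements, coords=atoms.coord.copy(),
                          radii=radii, chains=[str(c) for c in atoms.chain_id],
                          assembly_id=assembly or "1")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _blend(rgb: np.ndarray, toward, fraction: float) -> np.ndarray:
    toward = np.asarray(toward, dtype=float)
    return (rgb * (1 - fraction) + toward * fraction).astype(np.uint8)


def render(scene: Scene, path: str | Path | None, pixels_per_nm: float = 2.0,
           scale_bar_nm: float | None = None) -> Image.Image:
    """Deterministic raster of the scene (backgrounds, depth-cued layers,
    compartment fills, optional scale bar). Returns the image; writes a PNG
    when ``path`` is given. The scene is not mutated."""
    if pixels_per_nm <= 0:
        raise FormatError("pixels_per_nm must be > 0")
    w_nm, h_nm = scene.canvas
    W, H = int(round(w_nm * pixels_per_nm)), int(round(h_nm * pixels_per_nm))
    if W <= 0 or H <= 0:
        raise FormatError("zero-size canvas")
    img = Image.new("RGBA", (W, H), tuple(scene.background_color) + (255,))

    def to_px(p):
        return (W / 2 + p[0] * pixels_per_nm, H / 2 - p[1] * pixels_per_nm)

    for bg in sorted(scene.backgrounds.values(), key=lambda b: (b.z_order, b.id)):
        ref = Path(bg.image_ref)
        if not ref.exists():
            continue
        layer_img = Image.open(ref).convert("RGBA")
        factor = bg.nm_per_pixel * pixels_per_nm
        size = (max(1, int(layer_img.width * factor)),
                max(1, int(layer_img.height * factor)))
        layer_img = layer_img.resize(size, Image.NEAREST)
        if bg.rotation:
            layer_img = layer_img.rotate(np.degrees(bg.rotation), expand=True)
        if bg.opacity < 1.0:
            alpha = layer_img.getchannel("A").point(
                lambda a: int(a * bg.opacity))
            layer_img.putalpha(alpha)
        off = (int(W / 2 - layer_img.width / 2), int(H / 2 - layer_img.height / 2))
        img.alpha_composite(layer_img, off)

    draw = ImageDraw.Draw(img)
    for chain in scene.membrane_chains:
        if not chain.closed:
            continue
        pts, _ = chain.rail_points(scene.world)
        ing = scene.palette[chain.ingredient]
        fill = tuple(int(c * 255 * 0.35) for c in ing.color) + (160,)
        draw.polygon([to_px(p) for p in pts], fill=fill)

    hull_ids = {r.hull_body_id for r in scene.lock_regions.values()}
    for layer in (2, 1, 0):
        cue = defaults.DEPTH_CUE[layer]
        for bid in sorted(scene.instances):
            body = scene.world.bodies[bid]
            if body.layer != layer or bid in hull_ids:
                continue
            ing = scene.palette[body.ingredient]
            sprite = ing.sprite.image.copy()
            tint = (np.array(ing.color) * 255).astype(float)
            rgb = (sprite[:, :, :3].astype(float) * tint / 255.0)
            rgb = _blend(rgb, scene.background_color, cue)
            sprite[:, :, :3] = rgb
            s_img = Image.fromarray(sprite, "RGBA")
            factor = ing.sprite.nm_per_pixel * pixels_per_nm
            size = (max(1, int(s_img.width * factor)),
                    max(1, int(s_img.height * factor)))
            s_img = s_img.resize(size, Image.NEAREST)
            if abs(body.angle) > 1e-9:
                s_img = s_img.rotate(np.degrees(body.angle), expand=True,
                                     resample=Image.NEAREST)
            cx, cy = to_px(body.position)
            img.alpha_composite(s_img, (int(cx - s_img.width / 2),
                                        int(cy - s_img.height / 2)))

    if scale_bar_nm:
        bar_px = int(scale_bar_nm * pixels_per_nm)
        margin = max(4, H // 40)
        draw = ImageDraw.Draw(img)
        draw.rectangle([W - bar_px - margin, H - margin - 4, W - margin,
                        H - margin], fill=(255, 255, 255, 255))

    if path is not None:
        img.save(path)
    return img
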