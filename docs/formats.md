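# File formats (`format_version: 1`)

All on-disk formats are plain text (JSON / JSON-lines) plus RGBA PNG sprites.
Coordinates are nm, Y-up, world origin at the canvas center. Angles are rad.

## Recipe JSON

A recipe is a dictionary of compartments, each owning a palette of ingredient
definitions:

```json
{
  "format_version": 1,
  "name": "demo",
  "compartments": [
    {
      "name": "membrane",
      "ingredients": [
        {
          "name": "receptor",
          "kind": "membrane_bound",
          "sprite": "sprites/receptor.png",
          "nm_per_pixel": 0.25,
          "color": [0.9, 0.6, 0.4],
          "binding": {"thickness": 4.0, "surface_offset": 2.0, "padding": 0.5,
                      "rotation": 0.0}
        },
        {
          "name": "lipid",
          "kind": "fiber",
          "sprite": "sprites/lipid.png",
          "nm_per_pixel": 0.25,
          "fiber": {"spacing": 10.0, "preset": "membrane"}
        }
      ]
    }
  ]
}
```

- `kind`: `soluble` | `membrane_bound` | `fiber`.
- `sprite` paths are resolved relative to the recipe file.
- `binding` (membrane_bound only): `thickness`, `surface_offset`, `padding`
  (nm), `rotation` (rad). Alias keys `offset`, `surfaceOffset`,
  `membrane_thickness` are accepted.
- `fiber` (fiber only): `spacing` (nm), `subunit_rotation` (rad),
  `n_springs`, or a `preset` (`dna` = 10 springs, `rna` = 0, `membrane` = 3,
  `user` = 3). Aliases `repetition`, `twist`, `nSprings` are accepted.
- Unknown keys anywhere are preserved on round trip.
- Colliders are never stored; they are recomputed from the sprite at load.

## Scene text

Line-oriented JSON (one record per line, diff-friendly). The first line is the
header; instance positions are quantized to 3 decimals:

```
{"record": "scene", "format_version": 1, "canvas": [400.0, 400.0], ...}
{"record": "instance", "id": 0, "ingredient": "blob", "position": [10.0, -5.0],
 "angle": 0.0, "layer": 0, "pinned": false, "group_stamp": null, ...}
{"record": "fiber_chain", "ingredient": "dna", "ids": [3, 4, 5], "closed": false,
 "layers": [0, 0, 0]}
{"record": "membrane_chain", "ingredient": "lipid", "ids": [...], "closed": true,
 "end_pins": []}
{"record": "pin_to", "a": 0, "b": 1, "local_a": [0, 0], "local_b": [0, 0],
 "distance": 12.5}
{"record": "group", "id": 7, "members": [["blob", [0.0, 0.0], 0.0]], "pin_tos": []}
{"record": "lock", "id": 9, "members": [0, 1, 2]}
{"record": "background", "image_ref": "tomo.png", "nm_per_pixel": 0.36, ...}
```

Loading restores exact poses (no settling). Chain constraints (hinges,
persistence springs) and lock hulls are recomputed deterministically from the
stored member poses.

## Bundles

A `.zip` containing `scene.txt`, `recipe.json` and every sprite PNG under its
recipe-relative path. Bundles are hermetic: they load in an empty directory.

## Session scripts

```json
{"seed": 1, "commands": [
  {"cmd": "new-scene", "canvas": [300, 300]},
  {"cmd": "load-recipe", "path": "recipe.json"},
  {"cmd": "paint", "ingredient": "blob", "position": [0, 0], "layer": 0},
  {"cmd": "draw-membrane", "ingredient": "lipid", "points": [[x, y], ...]},
  {"cmd": "measure", "a": 0, "b": 1},
  {"cmd": "render", "path": "out.png", "pixels_per_nm": 2.0}
]}
```

Commands: `new-scene`, `load-recipe`, `ingredient`, `paint`, `draw-fiber`,
`draw-membrane`, `attach`, `pin`, `unpin`, `pin-to`, `group`, `stamp`,
`lock`, `unlock`, `nudge`, `erase`, `measure`, `diffuse`, `settle`,
`background`, `save`, `bundle`, `render`. Scripts are validated in full
before execution; the run writes `report.jsonl` with per-command copy
numbers and live measurements.
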