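# mesobrush

Headless, scriptable 2.5D mesoscale scene construction. Molecular
"ingredients" — soluble proteins, membrane-bound proteins and fiber subunits —
are built from atomic structures (PDB/mmCIF) or transparent images, given
automatically inferred 2D colliders, and then painted, constrained, grouped,
locked, measured, serialized and rendered on a three-layer canvas with a
deterministic position-based physics solver. No GUI, no game engine.

Highlights:

- **Collider inference**: eigen-decomposition of the sprite-contour
  covariance picks a circle or oriented rectangle per molecule
  (ratio threshold 1.15), sized from projected contour extents.
- **Fibers and membranes**: stroke paths become articulated hinge chains with
  persistence springs (presets: DNA 10, RNA 0, membrane 3, user default 3).
  Closed membrane strokes become clockwise vesicles with a triangulated
  interior compartment; open ends are pinned.
- **Membrane proteins**: three-way contour partition (exterior /
  intramembrane / interior), dual collider groups and a wheels-on-a-rail
  constraint that keeps proteins embedded, oriented and free to slide.
- **Scene tools**: paint, erase, pin, pin-to, group/stamp brushes, nudge,
  live distance measurements, copy numbers, scaled backgrounds, and a lock
  tool that turns off internal physics and substitutes Graham convex hulls
  over mean-shift clusters (8 nm cutoff) of member centers.
- **Serialization**: CellPACK-style recipe JSON, line-oriented scene text,
  hermetic zip bundles, deterministic PNG rendering with depth cueing.
  See `docs/formats.md`.

## Library quick start

```python
import numpy as np
from mesobrush import Scene, StrokePath, fixtures

scene = Scene(canvas=(400, 400))
for ing in fixtures.demo_ingredients(seed=0).values():
    scene.add_ingredient(ing)

vesicle = scene.draw_membrane(
    "lipid", StrokePath(fixtures.circle_stroke(60, clockwise=True)))
pid = scene.paint("receptor", (0, 55), settle=False)
scene.attach_to_membrane(pid, vesicle, arc_position=0.0)
scene.paint("blob", (0, 0))
scene.settle()

from mesobrush.io import render
render(scene, "scene.png", pixels_per_nm=2.0, scale_bar_nm=50)
```

## CLI

```bash
# deterministic synthetic fixtures (contours, toy structures, strokes, recipes)
mesobrush fixtures --kind recipe --out demo --seed 1

# build an ingredient bundle (sprite PNG + JSON sidecar) from a structure
mesobrush ingredient --input my.pdb --kind membrane_bound \
    --thickness 4 --offset 2 --nm-per-pixel 0.25 --out ing/

# run a scripted painting session (JSON commands; see docs/formats.md)
mesobrush run session.json --out results/ --seed 1
```

Session runs validate every command before executing anything, write a
JSON-lines report (copy numbers, live measurements), and exit non-zero on the
first error.

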