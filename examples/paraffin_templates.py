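"""Slice a bolus into 1.5 mm paraffin sheet templates.

Manual fabrication stacks paraffin sheets cut from per-layer paper
templates.  We slice a 6.75 mm tall box bolus: the ceiling rule gives five
layers with a partial 0.75 mm top sheet, and the rebuilt staircase solid
conserves the template volume exactly.
"""

import tempfile

from bolusforge import mesh_signed_volume, slice_paraffin_layers, staircase_solid
from bolusforge.bolus import export_templates
from bolusforge.geometry import TriMesh
import numpy as np
import trimesh

tm = trimesh.creation.box(
    extents=[30, 30, 6.75],
    transform=trimesh.transformations.translation_matrix([0, 0, 3.375]),
)
bolus = TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))

layers = slice_paraffin_layers(bolus, sheet=1.5)
print(f"layer count: {len(layers)} (heights: "
      f"{[round(t.thickness, 2) for t in layers]})")

out = tempfile.mkdtemp()
files = export_templates(layers, out)
print(f"wrote {len(files)} template files (true-scale SVG + CSV) to {out}")

stair = staircase_solid(layers)
print(f"staircase volume: {mesh_signed_volume(stair):.3f} mm^3 "
      f"(sum area x thickness: {sum(t.area * t.thickness for t in layers):.3f})")
# Each SVG outline is cut at the layer's mid-height, so stacking the sheets
# reproduces the smooth solid's volume without bias.
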