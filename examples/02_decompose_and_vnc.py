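"""Three-material decomposition: concentration map + virtual non-contrast.

Simulates a small dilution phantom, decomposes each voxel's HU pair into
air/water fractions and holmium concentration, and verifies that the VNC
image removes the holmium enhancement.
"""

import numpy as np

import hoquant as hq

FAST = dict(voxel_spacing=(3.0, 1.0, 1.0), slice_count=6)

spec = hq.AcquisitionSpec(voltage_pair="80/150Sn", phantom_diameter=20.0, **FAST)
pair, truth = hq.make_dilution_phantom([2.0, 6.0, 10.0], spec, seed=3)

basis = hq.MaterialBasis(holmium=hq.enhancement_model("80/150Sn", 20.0))
cmap, diag = hq.decompose_image(pair, basis)

print(f"basis condition number: {diag.condition_number:.1f}")
print("insert readout (decomposed concentration, mg/mL):")
for ins in truth.layout.inserts:
    roi = hq.RoiSpec("cylinder", ins.center, radius=ins.size[0])
    mask = hq.core.roi_mask(roi, cmap.shape, cmap.voxel_spacing)
    m = cmap.concentration[mask].mean()
    print(f"  known {ins.concentration:5.2f}  ->  measured {m:5.2f}")

body = truth.material_mask > 0
print(
    f"\nVNC over the body: mean {cmap.vnc_mixed[body].mean():+.2f} HU "
    f"(holmium virtually removed; water-equivalent background is ~0 HU)"
)
print(
    "Single-energy CT sees the inserts as bright; the VNC pair shows what a\n"
    "pre-contrast scan would have looked like, while the material image maps\n"
    "the holmium concentration voxel by voxel."
)
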