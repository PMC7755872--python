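"""Spectral calibration: fit holmium enhancement vectors from phantom scans.

Simulates the 10-cm calibration phantom (centric 10.5 mg/mL holmium syringe,
offset water syringe) for each tube-voltage pair, fits the enhancement
vector from the two ROIs, and shows the size trend of the holmium CT value.
"""

import hoquant as hq

# fast grid for a demo; drop these overrides for the paper-scale defaults
FAST = dict(voxel_spacing=(3.0, 1.0, 1.0), slice_count=6)

print("Fitted enhancement vectors at 10 cm (HU per mg/mL):")
for vp in ("70/150Sn", "80/150Sn", "100/150Sn", "80/140"):
    spec = hq.AcquisitionSpec(voltage_pair=vp, phantom_diameter=10.0, **FAST)
    pair, _ = hq.make_calibration_phantom(spec, seed=1, noise=hq.NO_NOISE)
    v = hq.calibrate_scan(pair, hq.REFERENCE_CONCENTRATION)
    print(f"  {vp:>10}:  e_low = {v.e_low:5.1f}   e_high = {v.e_high:5.1f}")

print("\nHolmium CT value at 10 mg/mL vs. phantom size (low-kV spectrum):")
for vp in ("80/150Sn", "100/150Sn"):
    row = [10.0 * hq.enhancement_model(vp, d).e_low for d in (10, 15, 20, 25, 30, 35)]
    print(f"  {vp:>10}: " + "  ".join(f"{x:6.1f}" for x in row))

print(
    "\nThe 70/80-kV values rise with object size (spectrum shifting toward\n"
    "holmium's 56-keV k-edge) while the harder spectra fall — the spectral\n"
    "separation the three-material decomposition relies on."
)
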