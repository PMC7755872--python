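"""Serial-dilution accuracy: linearity, tolerance verdicts, detection limit.

Calibrates on a noiseless calibration-phantom simulation, then runs the
9-point 0.125-10 mg/mL series at clinical dose and reports per-insert
accuracy against the quadrature tolerance T = sqrt(0.5^2 + (0.1 C)^2).
"""

import hoquant as hq

FAST = dict(slice_count=6, voxel_spacing=(3.0, 1.0, 1.0))

cfg = hq.PipelineConfig(
    experiment="calibration", voltage_pairs=("80/150Sn",), diameters_cm=(20.0,), **FAST
)
table = hq.calibrate_grid(cfg)

result, fit = hq.run_dilution_series(
    "80/150Sn", "clinical", table, seed=1, **FAST
)

print("known  measured   T      within tolerance")
for r in result.inserts:
    print(
        f"{r.known:6.3f}  {r.measured:7.3f}  {r.tolerance:5.3f}   {r.within_tolerance}"
    )
print(
    f"\nlinear fit: m = {fit.m:.2f}, b = {fit.b:.2f} mg/mL, "
    f"R^2 = {fit.r_squared:.2f}, RMSE = {fit.rmse:.2f} mg/mL"
)
print(
    "\nA slope of ~1 with near-zero offset means the decomposition recovers\n"
    "the true concentrations across two decades; every insert inside its\n"
    "tolerance band puts the detection limit at or below 0.125 mg/mL."
)
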