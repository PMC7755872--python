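"""Animal-like phantom: total-mass recovery of focal holmium deposits.

Simulates an elliptical body (~16.7 cm water-equivalent diameter) with four
injected deposits, decomposes with a size-interpolated calibrated vector,
segments the deposits, and compares detected vs. injected mass.
"""

import hoquant as hq
from hoquant.pipelines import run_animal_series

cfg = hq.PipelineConfig(experiment="animal", slice_count=12, voxel_spacing=(1.5, 1.0, 1.0))
cal = hq.PipelineConfig(
    experiment="calibration",
    voltage_pairs=("80/150Sn",),
    diameters_cm=(15.0, 20.0),
    slice_count=12,
    voxel_spacing=(1.5, 1.0, 1.0),
)
table = hq.calibrate_grid(cal)

result = run_animal_series(cfg, table, seed=1)

print("injection  injected (mg)  detected (mg)  relative deviation (%)")
for d in result.deposits:
    print(
        f"{d.deposit_id:9d}  {d.injected_mg:13.2f}  {d.detected_mg:13.1f}"
        f"  {d.relative_deviation_pct:+21.1f}"
    )
print(
    f"\ntotal: injected {result.total_injected:.2f} mg, "
    f"detected {result.total_detected:.1f} mg, "
    f"max |deviation| {result.max_abs_relative_deviation:.1f}%"
)
print(
    "\nEach row mirrors the injected-vs-detected bookkeeping used to verify\n"
    "that thresholded concentration maps integrate back to the administered\n"
    "microsphere mass — the quantity a post-therapy dosimetry chain starts from."
)
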