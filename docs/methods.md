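# Methods

## Scope and approach

`hoquant` implements the dual-energy CT (DECT) quantification chain for
holmium microspheres as a simulation-backed analysis pipeline. Because no
real dual-energy acquisitions of holmium phantoms are publicly deposited,
the package pairs the analysis (calibration, decomposition, quantification)
with a synthetic-data generator that emulates the statistical structure of
such acquisitions with known ground truth. Everything downstream of the
generator — vector fitting, the 2×2 material solve, VNC synthesis, tolerance
verdicts, mass integration — is exactly the code a user would point at real
co-registered low/high-kV volumes.

## Forward model (synthetic data)

The generator is phenomenological, not a photon-transport simulation:

* **Geometry.** Three phantom classes, rasterized by voxel-centre
  containment on a phantom-centred grid (slice, row, column; default 20
  slices of 1.5 × 0.5 × 0.5 mm): a 10-cm water-equivalent calibration
  cylinder with a centric 2-cm holmium syringe (10.5 mg/mL by default) and a
  water syringe 3 cm off-centre; a 20-cm dilution cylinder with up to eight
  2-cm-scale inserts equiangular at 5 cm radius; and an elliptical
  animal-like body (semi-axes 70 × 100 mm, axis ratio 0.7, water-equivalent
  diameter ≈ 16.7 cm) with ellipsoidal deposits. Slice count and spacing are
  free parameters; the defaults are the package's own desk-scale choice and
  are what the shipped tests and replication script use.
* **HU values.** Air −1000 HU, water-equivalent background 0 HU, and a voxel
  at holmium concentration `c` reads `c · e_s(D)` over water, where
  `e_s(D)` is the per-spectrum enhancement at water-equivalent diameter `D`.
  Stored values are floored at −1024 HU (CT integer convention).
* **Enhancement surface.** `e_s(D)` is linear in `D`:
  `e_s(D) = base_s + slope_s · (D − 10 cm)`. Defaults (HU per mg/mL at
  10 cm): 44 (70 kV), 40 (80 kV), 34 (100 kV), 24 (140 kV), 16 (150Sn kV);
  slopes +0.20, +0.15, −0.12, −0.15, −0.12 per cm respectively. The signs
  encode the k-edge physics: growing object size hardens the spectrum toward
  holmium's 56-keV k-edge, increasing enhancement at 70/80 kV and decreasing
  it for the harder spectra. The absolute magnitudes are declared package
  configuration — chosen once so that the 80-kV SNR at 10 mg/mL lands in the
  tens (≈16 at clinical dose, ≈53 at high dose in a 20-cm body), the order
  observed on real third-generation dual-source systems. Linearity in `D`
  also makes the calibration table's linear diameter interpolation exact,
  which keeps the animal-phantom closed loop honest. All acceptance-style
  checks run the full calibrate-then-decompose loop, so conclusions do not
  hinge on these exact defaults.
* **Noise.** Additive voxelwise-independent Gaussian noise per spectrum with
  `σ(mAs) = σ_ref · sqrt(mAs_ref / mAs)` — image noise scales with the
  square root of dose reduction. Defaults: σ_ref = 25 HU (low-kV) and 20 HU
  (high-kV) at 100 mAs. Effective tube currents come from versioned presets
  (per voltage pair: the size series for calibration scans; clinical /
  high-dose pairs for quantification scans). Inter-spectrum noise
  correlation is configurable and defaults to 0. Generation is seeded and
  bit-reproducible.
* **Mass bookkeeping.** An animal deposit is specified by (mass, centre,
  volume). After rasterization the concentration is renormalized to
  `mass / (rasterized volume)`, so the ground-truth voxel-sum mass equals
  the requested injected mass exactly and mass recovery is tested against an
  exact reference rather than a discretization-polluted one.

Not modelled (deliberately): polychromatic transport / Beer–Lambert physics,
sinogram formation and filtered backprojection, beam hardening, blooming,
partial-volume mixing at insert rims (voxels are all-or-nothing; analysis
ROIs are eroded 2 mm instead), scanner-specific detector effects. Passing
tests therefore demonstrate the *algorithmic* correctness and noise
behaviour of the chain, not robustness to reconstruction artifacts.

## Calibration

The enhancement vector is a water-referenced two-point calibration through
the origin: `e = (mean_Ho − mean_water) / C_ref` per spectrum, with both
means taken over identical eroded ROIs (≥ 25 voxels). The water reference
makes the fit invariant to any global HU offset. Fits whose spectral
separation `|e_low − e_high|` falls at or below 1 HU/(mg/mL) are rejected as
degenerate. Vectors are stored per (voltage pair, diameter); lookups of
missing keys fail loudly, and linear interpolation between bracketing
diameters must be requested explicitly (no extrapolation). For an object
between calibrated sizes — the animal body's water-equivalent diameter —
interpolation is the intended path. Pipeline calibration scans default to
σ = 0: with noise, the ROI-mean error shrinks as 1/√n and is negligible at
the shipped ROI sizes, but the noiseless default makes the table exactly
reproducible.

## Decomposition

With two measurements and three materials the system is closed by volume
conservation of the air/water mixture (`f_air + f_water = 1`), holmium
entering as an additive enhancement. This reproduces the air and water base
points exactly and reduces the "orthogonalized base transformation" to an
exact 2×2 linear solve — equivalent for any non-singular basis, with no
iterative projection. Consequences worth knowing:

* concentration depends only on the HU difference:
  `c = (P_low − P_high) / (e_low − e_high)`, so the per-voxel concentration
  noise is `sqrt(σ_low² + σ_high²) / |e_low − e_high|` (implemented as the
  general 2×2 propagation, including optional noise correlation);
* noise-driven negative concentrations are preserved by default so ROI means
  stay unbiased; an optional clip floors the emitted map at 0 *after* VNC
  computation (display maps);
* VNC is produced per spectrum (`P − c·e`) plus a mixed volume (default
  50/50; the mixing weight is a free display choice);
* diagnostics record the basis condition number and the fractions of clipped
  voxels and of voxels with air fraction outside [0, 1].

Any third material present in a real scan is absorbed into the two base
directions — a known limitation of two-spectra three-material separation.

## Quantification

* **Tolerance.** `T(C) = sqrt(0.5² + (0.1·C)²)` mg/mL, the quadrature sum of
  a CT-value-stability term and a spectral-stability term; a measurement
  passes when `|measured − known| ≤ T(known)`.
* **Dilution fits.** Ordinary least squares of measured on known
  concentration (known as abscissa). R² = 1 − SS_res/SS_tot; RMSE is the
  root mean squared residual *about the fitted line* (not about the
  identity), which is why a nonzero offset can coexist with a small RMSE.
  The 9-point series is simulated in two scan groups (0.125–1.0 and
  2.0–10.0 mg/mL) and fitted jointly.
* **SNR.** ROI mean divided by within-ROI sd of the same volume; constant
  image noise then yields the concentration-proportional SNR behaviour.
  Undefined (error) on noiseless data.
* **Mass recovery.** Deposits are segmented by thresholding the
  concentration map at T(0) = 0.5 mg/mL followed by one binary closing. The
  threshold is applied to a Gaussian-smoothed copy of the map (default 4 mm
  FWHM), because at clinical-dose noise the per-voxel concentration sd
  (≈1.4–1.5 mg/mL) exceeds the threshold and a raw cut would select ~37% of
  background voxels — above the 3-D percolation threshold, making the mask
  meaningless. Smoothing affects the mask only; mass always integrates the
  unsmoothed map (mg/mL × voxel mL), so rim voxels contribute zero-mean
  noise rather than bias. Segmented voxels are attributed to the nearest
  ground-truth deposit centre so merged components are split, and the
  threshold is configurable for sensitivity checks.
* **Report rounding.** CSV reports round concentrations and deviations to
  one decimal and fit statistics to two decimals; all in-memory results stay
  at full precision.

## Replication studies (scripts/acceptance.py)

The script reruns the whole chain at the default volumes: noiseless spectral
calibration; the 9-point dilution series at 80/150Sn high dose (10 seeds,
mean slope), all four voltage pairs at clinical dose (10 seeds for the
low-kV HU linearity R², 20 seeds for the tolerance-based detection limit);
and the four-deposit animal phantom (injected masses 5.61, 3.34, 5.96,
12.59 mg; 10 seeds) for the maximum absolute mass deviation. All randomness
derives from the single `--seed` argument. Problem sizes (20 slices, the
seed counts above) are the package's desk-scale defaults.

## Numerical choices and degenerate inputs

* Seeds: `numpy.random.default_rng` (PCG64); child seeds via
  `SeedSequence([parent, stage, …])`, all below 2³¹.
* ROI erosion is analytic (the convex shape is shrunk by the margin), exact
  for cylinders/spheres/ellipsoids; ROIs extending beyond the volume raise
  geometry errors rather than silently cropping.
* Basis matrices are rejected when the holmium vector is (near-)parallel to
  the water−air direction or the condition number exceeds a cap.
* Degenerate regressions (constant abscissa), empty masks, empty calibration
  tables, ROIs < 25 voxels, inserts outside the body or overlapping, and
  unknown voltage/size keys all raise typed errors.
* The −1024 HU floor truncates the noise distribution in air at clinical
  noise levels and biases the air mean upward by ~2 HU; the air/water
  mean-convergence property is therefore validated in the low-noise regime
  where the clamp is inactive. No analysis ROI sits near the floor.

## Known limitations

* No reconstruction physics: conclusions about beam hardening, blooming, or
  elliptical-body artifacts seen on real scanners are out of reach of this
  generator by design.
* Noise is homoscedastic within a scan; real auto-exposure noise varies
  axially and radially.
* The enhancement magnitudes are configuration, not measured physics; only
  their linear concentration scaling, size trends, and the calibration /
  decomposition closed loop are asserted.
* Two-spectra decomposition cannot separate a fourth material (e.g. iodine
  plus holmium); that requires more spectral channels.
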