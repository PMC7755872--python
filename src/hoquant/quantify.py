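"""Quantitative evaluation: tolerance term, SNR, dilution fits, mass recovery.

The tolerance for a quantified concentration combines, in quadrature, a fixed
CT-value-stability term of 0.5 mg/mL and a spectral-stability term of 10% of
the known concentration:

    T(C_known) = sqrt((0.5 mg/mL)^2 + (0.1 * C_known)^2)

A measurement is "within tolerance" when |measured - known| <= T(known).
Serial-dilution accuracy is summarized by an ordinary least-squares fit of
measured on known concentration (slope m, offset b, R^2, RMSE about the
fitted line). Total deposited mass integrates the concentration map over a
segmented deposit mask (mg/mL x mL per voxel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .core import GroundTruth, RoiSpec, roi_mask
from .decompose import ConcentrationMap
from .errors import (
    DomainError,
    PairingError,
    RankError,
    SegmentationError,
    UndefinedSNRError,
)

#: Default deposit-segmentation threshold: the zero-concentration tolerance.
MASS_THRESHOLD = 0.5  # mg/mL


def tolerance(c_known):
    """Quantification tolerance T (mg/mL) at a known concentration.

    Accepts scalars or arrays; strictly increasing in ``c_known`` with
    T(0) = 0.5 mg/mL.
    """
    c = np.asarray(c_known, dtype=float)
    if np.any(c < 0):
        raise DomainError("known concentration must be >= 0")
    t = np.sqrt(0.5**2 + (0.1 * c) ** 2)
    return float(t) if np.isscalar(c_known) else t


def relative_deviation(detected: float, injected: float) -> float:
    """Relative deviation (%) of a detected amount w.r.t. the injected amount."""
    if injected <= 0:
        raise DomainError("injected amount must be > 0")
    return 100.0 * (detected - injected) / injected


def snr(volume: np.ndarray, roi) -> float:
    """ROI mean divided by within-ROI standard deviation of the same volume.

    ``roi`` is either a boolean mask or an (RoiSpec, spacing) tuple.
    """
    if isinstance(roi, tuple):
        spec, spacing = roi
        mask = roi_mask(spec, volume.shape, spacing)
    else:
        mask = roi
    vals = volume[mask]
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise UndefinedSNRError("ROI standard deviation is zero (noiseless region)")
    return float(vals.mean()) / sd


@dataclass(frozen=True)
class FitStats:
    """Linear-fit parameters and errors of measured vs. known concentration."""

    m: float  # slope, dimensionless
    b: float  # offset, mg/mL
    r_squared: float
    rmse: float  # mg/mL, residuals about the fitted line
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise RankError("fit needs at least two points")
        if self.rmse < 0 or self.r_squared > 1 + 1e-12:
            raise ValueError("inconsistent fit statistics")


def linear_fit(known: Sequence[float], measured: Sequence[float]) -> FitStats:
    """OLS of measured on known; R^2 = 1 - SS_res/SS_tot; RMSE about the line."""
    x = np.asarray(known, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size:
        raise PairingError("known and measured series differ in length")
    if x.size < 2 or np.unique(x).size < 2:
        raise RankError("need >= 2 distinct known concentrations")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / x.size))
    return FitStats(m=float(res.slope), b=float(res.intercept), r_squared=r2, rmse=rmse, n=int(x.size))


@dataclass(frozen=True)
class InsertRecord:
    """One dilution insert: known vs. measured concentration."""

    known: float  # mg/mL
    measured: float  # mg/mL (ROI mean)
    sd: float  # mg/mL (ROI sd)
    n_voxels: int
    tolerance: float  # mg/mL, T(known)
    within_tolerance: bool
    absolute_deviation: float  # mg/mL
    relative_deviation: float | None  # %, None for known == 0


@dataclass
class DilutionResult:
    """Per-insert accuracy records of one decomposed dilution series."""

    inserts: list[InsertRecord]
    voltage_pair: str = ""
    dose_mode: str = ""

    @property
    def all_within_tolerance(self) -> bool:
        return all(r.within_tolerance for r in self.inserts)

    def known(self) -> list[float]:
        return [r.known for r in self.inserts]

    def measured(self) -> list[float]:
        return [r.measured for r in self.inserts]


def _insert_rois(truth: GroundTruth, erosion_margin: float = 2.0) -> list[RoiSpec]:
    rois = []
    for ins in truth.layout.inserts:
        if ins.shape == "cylinder":
            rois.append(
                RoiSpec(shape="cylinder", center=ins.center, radius=ins.size[0], erosion_margin=erosion_margin)
            )
        else:
            rois.append(RoiSpec(shape="ellipsoid", center=ins.center, semi_axes=ins.size, erosion_margin=erosion_margin))
    return rois


def evaluate_dilution(
    cmap: ConcentrationMap,
    truth: GroundTruth,
    rois: Sequence[RoiSpec] | None = None,
    *,
    voltage_pair: str = "",
    dose_mode: str = "",
) -> tuple[DilutionResult, FitStats]:
    """Per-insert tolerance verdicts plus the series' linear fit.

    ROIs default to the ground-truth insert geometry eroded by 2 mm; an
    explicit list must pair one-to-one with the truth inserts.
    """
    if rois is None:
        rois = _insert_rois(truth)
    if len(rois) != len(truth.layout.inserts):
        raise PairingError(
            f"{len(rois)} ROIs for {len(truth.layout.inserts)} ground-truth inserts"
        )
    records = []
    for roi, ins in zip(rois, truth.layout.inserts):
        mask = roi_mask(roi, cmap.shape, cmap.voxel_spacing)
        vals = cmap.concentration[mask]
        measured = float(vals.mean())
        known = float(ins.concentration)
        t = tolerance(known)
        dev = measured - known
        records.append(
            InsertRecord(
                known=known,
                measured=measured,
                sd=float(vals.std(ddof=1)),
                n_voxels=int(mask.sum()),
                tolerance=t,
                within_tolerance=bool(abs(dev) <= t),
                absolute_deviation=float(dev),
                relative_deviation=relative_deviation(measured, known) if known > 0 else None,
            )
        )
    result = DilutionResult(inserts=records, voltage_pair=voltage_pair, dose_mode=dose_mode)
    fit = linear_fit(result.known(), result.measured())
    return result, fit


# ---------------------------------------------------------------------------
# mass recovery


def total_mass(
    concentration: np.ndarray | ConcentrationMap,
    deposit_mask: np.ndarray,
    voxel_spacing: Sequence[float] | None = None,
) -> float:
    """Total holmium mass (mg) over a mask: sum of mg/mL x voxel mL."""
    if isinstance(concentration, ConcentrationMap):
        spacing = concentration.voxel_spacing
        conc = concentration.concentration
    else:
        if voxel_spacing is None:
            raise DomainError("voxel_spacing required with a bare array")
        spacing = voxel_spacing
        conc = concentration
    if not deposit_mask.any():
        raise SegmentationError("deposit mask is empty")
    vv = float(np.prod(spacing)) / 1000.0
    return float(conc[deposit_mask].sum() * vv)


def segment_deposits(
    cmap: ConcentrationMap,
    threshold: float = MASS_THRESHOLD,
    smoothing_fwhm_mm: float = 4.0,
    closing_iterations: int = 1,
) -> np.ndarray:
    """Threshold-based deposit segmentation of a concentration map.

    The mask is determined on a Gaussian-smoothed copy of the map (default
    4 mm FWHM) so that voxelwise noise does not percolate through the
    threshold; mass readout always integrates the *unsmoothed* map.
    Connected components are labelled after one binary closing.
    """
    conc = cmap.concentration
    if smoothing_fwhm_mm > 0:
        sigma_vox = [smoothing_fwhm_mm / 2.3548 / s for s in cmap.voxel_spacing]
        smooth = ndimage.gaussian_filter(conc, sigma=sigma_vox)
    else:
        smooth = conc
    mask = smooth >= threshold
    if closing_iterations > 0 and mask.any():
        mask = ndimage.binary_closing(mask, iterations=closing_iterations)
    if not mask.any():
        raise SegmentationError("no voxels above the segmentation threshold")
    labels, _ = ndimage.label(mask)
    return labels


@dataclass(frozen=True)
class DepositRecord:
    """One deposit: injected vs. detected holmium mass."""

    deposit_id: int
    injected_mg: float
    detected_mg: float
    relative_deviation_pct: float


@dataclass
class MassResult:
    """Injected-vs-detected mass bookkeeping of an animal-style phantom."""

    deposits: list[DepositRecord]
    threshold: float = MASS_THRESHOLD

    @property
    def total_injected(self) -> float:
        return sum(d.injected_mg for d in self.deposits)

    @property
    def total_detected(self) -> float:
        return sum(d.detected_mg for d in self.deposits)

    @property
    def max_abs_relative_deviation(self) -> float:
        return max(abs(d.relative_deviation_pct) for d in self.deposits)


def evaluate_mass(
    cmap: ConcentrationMap,
    truth: GroundTruth,
    threshold: float = MASS_THRESHOLD,
    smoothing_fwhm_mm: float = 4.0,
) -> MassResult:
    """Segment deposits, integrate their mass, and compare with the truth.

    Each segmented voxel is attributed to the nearest ground-truth deposit
    centre, so merged components are split rather than double-counted.
    """
    if not truth.masses_mg:
        raise SegmentationError("ground truth contains no deposits")
    seg = segment_deposits(cmap, threshold=threshold, smoothing_fwhm_mm=smoothing_fwhm_mm)
    mask = seg > 0
    # attribute by nearest deposit centre (voxel-index space scaled to mm)
    centers = {}
    for k in truth.masses_mg:
        idx = np.argwhere(truth.deposit_labels == k)
        centers[k] = idx.mean(axis=0) * np.asarray(truth.voxel_spacing)
    ids = sorted(centers)
    vox = np.argwhere(mask) * np.asarray(truth.voxel_spacing)
    d2 = np.stack([((vox - centers[k]) ** 2).sum(axis=1) for k in ids], axis=1)
    nearest = np.asarray(ids)[np.argmin(d2, axis=1)]
    vv = cmap.voxel_volume_ml
    records = []
    flat = cmap.concentration[mask]
    for k in ids:
        detected = float(flat[nearest == k].sum() * vv)
        injected = truth.masses_mg[k]
        records.append(
            DepositRecord(
                deposit_id=k,
                injected_mg=injected,
                detected_mg=detected,
                relative_deviation_pct=relative_deviation(detected, injected),
            )
        )
    return MassResult(deposits=records, threshold=threshold)
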