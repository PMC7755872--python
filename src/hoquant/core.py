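"""Shared domain types for the dual-energy holmium quantification pipeline.

Conventions used throughout the package:

* Volumes are 3-D ``numpy`` arrays ordered ``(slice, row, column)`` with voxel
  spacing in millimetres given in the same order.
* World coordinates are phantom-centred: voxel ``i`` along an axis with ``n``
  voxels and spacing ``s`` sits at ``(i - (n - 1) / 2) * s`` mm.
* CT numbers are Hounsfield units (HU): water 0, air -1000, stored with a
  floor clamp at -1024 (CT integer convention).
* Concentrations are mg holmium per mL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError, RegistrationError, RoiError

HU_FLOOR = -1024.0
AIR_HU = -1000.0
WATER_HU = 0.0

_PRESETS = None


def load_presets() -> dict:
    """Load the versioned acquisition presets shipped with the package."""
    global _PRESETS
    if _PRESETS is None:
        text = resources.files("hoquant").joinpath("data/presets.json").read_text()
        _PRESETS = json.loads(text)
    return _PRESETS


def voltage_pairs() -> tuple[str, ...]:
    return tuple(load_presets()["voltage_pairs"])


def spectra_of(voltage_pair: str) -> tuple[str, str]:
    """Return the (low-kV, high-kV) spectrum labels of a tube-voltage pair."""
    pairs = load_presets()["voltage_pairs"]
    if voltage_pair not in pairs:
        raise ConfigurationError(
            f"unknown tube-voltage pair {voltage_pair!r}; expected one of {sorted(pairs)}"
        )
    low, high = pairs[voltage_pair]
    return low, high


def calibration_diameters() -> tuple[float, ...]:
    return tuple(float(d) for d in load_presets()["calibration_diameters_cm"])


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition metadata of a simulated dual-energy scan.

    Parameters
    ----------
    voltage_pair:
        One of ``70/150Sn``, ``80/150Sn``, ``100/150Sn``, ``80/140`` (kV).
    dose_mode:
        ``"clinical"`` (automatic exposure control level) or ``"high"``.
    phantom_diameter:
        Calibration phantom diameter in cm (one of 10/15/20/25/30/35) or the
        string ``"animal"`` for the elliptical animal-like phantom.
    tube_current:
        Optional explicit (low-tube, high-tube) effective mAs; when ``None``
        the preset tables are consulted.
    voxel_spacing:
        (slice, row, column) spacing in mm.
    slice_count:
        Number of axial slices simulated.
    """

    voltage_pair: str = "80/150Sn"
    dose_mode: str = "clinical"
    phantom_diameter: float | str = 20.0
    tube_current: tuple[float, float] | None = None
    voxel_spacing: tuple[float, float, float] = (1.5, 0.5, 0.5)
    slice_count: int = 20

    def __post_init__(self) -> None:
        spectra_of(self.voltage_pair)  # validates the pair
        if self.dose_mode not in ("clinical", "high"):
            raise ConfigurationError(f"dose_mode must be clinical|high, got {self.dose_mode!r}")
        if self.phantom_diameter != "animal":
            d = float(self.phantom_diameter)
            if d not in calibration_diameters():
                raise ConfigurationError(
                    f"phantom_diameter must be one of {calibration_diameters()} cm or 'animal', got {d}"
                )
        if self.slice_count < 1:
            raise ConfigurationError("slice_count must be a positive integer")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("all voxel spacings must be > 0")

    def resolve_tube_current(self, context: str = "quantification") -> tuple[float, float]:
        """Effective (low, high) tube mAs, from ``tube_current`` or the presets.

        ``context`` selects the preset table: calibration scans use the
        size-dependent exposure series, quantification scans the
        clinical/high-dose series. Animal scans fall back to the
        quantification table (the cadaver is quantified with the phantom
        protocol).
        """
        if self.tube_current is not None:
            return tuple(float(x) for x in self.tube_current)  # type: ignore[return-value]
        p = load_presets()
        if context == "calibration" and self.phantom_diameter != "animal":
            key = str(int(float(self.phantom_diameter)))
            mas = p["calibration_tube_current_mas"][self.voltage_pair][key]
        else:
            mas = p["quantification_tube_current_mas"][self.voltage_pair][self.dose_mode]
        return float(mas[0]), float(mas[1])


@dataclass(frozen=True)
class NoiseModel:
    """Dose-scaled additive Gaussian image noise.

    The per-spectrum noise standard deviation follows
    ``sigma(dose) = sigma_ref * sqrt(dose_ref / dose)`` — image noise scales
    with the square root of the dose reduction. Noise is voxelwise
    independent; a correlation coefficient between the two spectra is
    configurable (0 by default).
    """

    sigma_ref: tuple[float, float] = (25.0, 20.0)  # HU at dose_ref, (low, high)
    dose_ref: float = 100.0  # mAs
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_ref <= 0:
            raise ConfigurationError("dose_ref must be > 0")
        if any(s < 0 for s in self.sigma_ref):
            raise ConfigurationError("sigma_ref components must be >= 0")
        if not -1.0 <= self.correlation <= 1.0:
            raise ConfigurationError("correlation must lie in [-1, 1]")

    def sigma(self, dose_mas: tuple[float, float]) -> tuple[float, float]:
        """Noise sd (HU) for a (low, high) tube current in mAs."""
        if any(d <= 0 for d in dose_mas):
            raise ConfigurationError("tube currents must be > 0 mAs")
        return tuple(
            s * float(np.sqrt(self.dose_ref / d)) for s, d in zip(self.sigma_ref, dose_mas)
        )  # type: ignore[return-value]


#: Noiseless acquisition (forward model only).
NO_NOISE = NoiseModel(sigma_ref=(0.0, 0.0))


@dataclass(frozen=True)
class EnhancementVector:
    """Per-unit-concentration HU enhancement of a material at the two spectra.

    The pair ``(e_low, e_high)`` is the material's signature in dual-energy
    space: the HU increment per mg/mL over water at the low- and high-kV
    spectrum. Holmium's 56-keV k-edge makes the two components differ, which
    is what the decomposition exploits.
    """

    material: str
    e_low: float
    e_high: float
    voltage_pair: str
    diameter_cm: float
    reference_concentration: float | None = None  # mg/mL used during calibration

    def __post_init__(self) -> None:
        if self.reference_concentration is not None and self.reference_concentration <= 0:
            raise ConfigurationError("reference_concentration must be > 0")

    @property
    def separation(self) -> float:
        return abs(self.e_low - self.e_high)

    def as_array(self) -> np.ndarray:
        return np.array([self.e_low, self.e_high], dtype=float)


@dataclass(frozen=True)
class RoiSpec:
    """A measurement region of interest in world coordinates (mm).

    ``erosion_margin`` shrinks the nominal shape before voxels are collected,
    suppressing partial-volume rim voxels (default 2 mm).
    """

    shape: str  # cylinder | sphere | ellipsoid
    center: tuple[float, float, float]  # (z, y, x) mm
    radius: float | None = None  # cylinder / sphere
    semi_axes: tuple[float, float, float] | None = None  # ellipsoid (z, y, x) mm
    half_length: float | None = None  # cylinder z half-extent; None = full stack
    erosion_margin: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "sphere", "ellipsoid"):
            raise RoiError(f"unknown ROI shape {self.shape!r}")
        if self.erosion_margin < 0:
            raise RoiError("erosion_margin must be >= 0")
        if self.shape in ("cylinder", "sphere"):
            if self.radius is None or self.radius <= self.erosion_margin:
                raise RoiError("radius must exceed erosion_margin")
        elif self.semi_axes is None or min(self.semi_axes) <= self.erosion_margin:
            raise RoiError("every semi-axis must exceed erosion_margin")


def world_axes(shape: tuple[int, int, int], spacing: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phantom-centred world coordinates (mm) of voxel centres, per axis."""
    return tuple(
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    )  # type: ignore[return-value]


def roi_mask(roi: RoiSpec, shape: tuple[int, int, int], spacing: Sequence[float]) -> np.ndarray:
    """Boolean voxel mask of an eroded ROI; raises if empty/too small.

    Erosion is analytic (the parametric shape is shrunk by the margin), which
    is exact for the convex shapes supported here.
    """
    z, y, x = world_axes(shape, spacing)
    cz, cy, cx = roi.center
    m = roi.erosion_margin
    if roi.shape == "cylinder":
        r = roi.radius - m
        in_plane = (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2 <= r**2
        if roi.half_length is None:
            axial = np.ones_like(z, dtype=bool)
        else:
            axial = np.abs(z - cz) <= max(roi.half_length - m, 0.0)
        mask = axial[:, None, None] & in_plane[None, :, :]
    elif roi.shape == "sphere":
        r = roi.radius - m
        mask = (
            (z[:, None, None] - cz) ** 2
            + (y[None, :, None] - cy) ** 2
            + (x[None, None, :] - cx) ** 2
        ) <= r**2
    else:
        a, b, c = (s - m for s in roi.semi_axes)
        mask = (
            ((z[:, None, None] - cz) / a) ** 2
            + ((y[None, :, None] - cy) / b) ** 2
            + ((x[None, None, :] - cx) / c) ** 2
        ) <= 1.0
    # an ROI that sticks out of the volume is a geometry error, not a silent crop
    half = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    extents = {
        "cylinder": (roi.half_length if roi.half_length is not None else 0.0, roi.radius, roi.radius),
        "sphere": (roi.radius,) * 3,
        "ellipsoid": roi.semi_axes or (0.0, 0.0, 0.0),
    }[roi.shape]
    for c0, e, h in zip(roi.center, extents, half):
        if abs(c0) + e - roi.erosion_margin > h + 1e-9:
            raise GeometryError("ROI exceeds volume bounds")
    n = int(mask.sum())
    if n < 25:
        raise RoiError(f"ROI contains only {n} voxels after erosion (need >= 25)")
    return mask


@dataclass(frozen=True)
class Insert:
    """A cylindrical or ellipsoidal region of known concentration."""

    shape: str  # cylinder | ellipsoid
    center: tuple[float, float, float]  # (z, y, x) mm
    size: tuple[float, ...]  # cylinder: (radius,); ellipsoid: (az, ay, ax) mm
    concentration: float  # mg/mL

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise GeometryError("insert concentration must be >= 0")
        if self.shape not in ("cylinder", "ellipsoid"):
            raise GeometryError(f"unknown insert shape {self.shape!r}")

    @property
    def in_plane_radius(self) -> float:
        return self.size[0] if self.shape == "cylinder" else max(self.size[1:])


@dataclass(frozen=True)
class PhantomLayout:
    """Body outline plus inserts, all in phantom-centred mm coordinates."""

    background_material: str  # water | air
    body_semi_axes: tuple[float, float]  # (y, x) mm; circle when equal
    inserts: tuple[Insert, ...] = ()

    def __post_init__(self) -> None:
        if self.background_material not in ("water", "air"):
            raise GeometryError("background_material must be water or air")
        by, bx = self.body_semi_axes
        for ins in self.inserts:
            _, cy, cx = ins.center
            r = ins.in_plane_radius
            # conservative containment: shrink the body outline by the insert radius
            if min(by, bx) <= r or (cy / (by - r)) ** 2 + (cx / (bx - r)) ** 2 > 1.0:
                raise GeometryError(f"insert at {ins.center} extends outside the body outline")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                dist = float(np.hypot(a.center[1] - b.center[1], a.center[2] - b.center[2]))
                if dist < a.in_plane_radius + b.in_plane_radius:
                    raise GeometryError("insert regions overlap")

    @property
    def water_equivalent_diameter_cm(self) -> float:
        """Diameter (cm) of the circle with the same cross-sectional area."""
        by, bx = self.body_semi_axes
        return 2.0 * float(np.sqrt(by * bx)) / 10.0


@dataclass
class GroundTruth:
    """Voxelwise truth accompanying a simulated image pair."""

    concentration: np.ndarray  # mg/mL
    material_mask: np.ndarray  # 0 air, 1 water-equivalent, 2 holmium-bearing
    deposit_labels: np.ndarray  # 0 background, k >= 1 per deposit/insert
    masses_mg: dict[int, float]  # deposit label -> total holmium mass (mg)
    layout: PhantomLayout
    voxel_spacing: tuple[float, float, float]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing)) / 1000.0

    def mass_of(self, label: int) -> float:
        """Voxel-sum mass (mg) of one deposit; equals ``masses_mg[label]``."""
        sel = self.deposit_labels == label
        return float(self.concentration[sel].sum() * self.voxel_volume_ml)


@dataclass
class ImagePair:
    """Co-registered low-/high-kV HU volumes plus acquisition metadata."""

    low: np.ndarray
    high: np.ndarray
    acquisition: AcquisitionSpec
    seed: int | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    noise_sigma: tuple[float, float] = (0.0, 0.0)  # realized sd (HU) per spectrum

    def __post_init__(self) -> None:
        if self.low.shape != self.high.shape:
            raise RegistrationError("low- and high-kV volumes have different shapes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.low.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.acquisition.voxel_spacing

    def roi_stats(self, roi: RoiSpec) -> tuple[float, float, float, float, int]:
        """(mean_low, mean_high, sd_low, sd_high, n) over the eroded ROI."""
        mask = roi_mask(roi, self.shape, self.spacing)
        lo, hi = self.low[mask], self.high[mask]
        return (
            float(lo.mean()),
            float(hi.mean()),
            float(lo.std(ddof=1)),
            float(hi.std(ddof=1)),
            int(mask.sum()),
        )
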