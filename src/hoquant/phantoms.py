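"""Seeded simulation of dual-energy CT phantom acquisitions.

Three phantom classes are generated, mirroring a spectral-calibration
phantom (10-cm water-equivalent cylinder with a centric holmium syringe and
an offset water syringe), a 20-cm dilution phantom with equiangular
concentration inserts, and an elliptical animal-like phantom with focal
holmium deposits of known total mass.

The forward model is phenomenological and deliberately simple:

* every voxel's noiseless HU value is ``background + c * e_s(D)`` where ``c``
  is the local holmium concentration (mg/mL) and ``e_s(D)`` the per-spectrum
  enhancement (HU per mg/mL) at water-equivalent diameter ``D``;
* enhancement varies linearly with object diameter, increasing for the soft
  70/80-kV spectra (mean energy shifting toward holmium's 56-keV k-edge) and
  decreasing for the harder 100/140/150Sn spectra (shifting beyond it);
* image noise is additive, voxelwise-independent Gaussian with
  ``sigma = sigma_ref * sqrt(dose_ref / mAs)`` per spectrum.

No sinogram/filtered-backprojection step, beam hardening or blooming is
modelled; HU values are clamped at the CT floor of -1024.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AIR_HU,
    HU_FLOOR,
    WATER_HU,
    AcquisitionSpec,
    EnhancementVector,
    GroundTruth,
    ImagePair,
    Insert,
    NoiseModel,
    PhantomLayout,
    calibration_diameters,
    spectra_of,
    world_axes,
)
from .errors import ConfigurationError, GeometryError

#: Default holmium reference concentration of the calibration syringe (mg/mL).
REFERENCE_CONCENTRATION = 10.5

#: Paper-style serial dilution series (mg holmium / mL).
DILUTION_SERIES = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

#: The two groups the series is scanned in (low and high concentration).
DILUTION_GROUPS = ((0.125, 0.25, 0.5, 1.0), (2.0, 4.0, 6.0, 8.0, 10.0))


@dataclass(frozen=True)
class EnhancementConfig:
    """Configured holmium enhancement surface e_s(D).

    ``base`` is the HU enhancement per mg/mL at the 10-cm reference diameter
    for each spectrum label; ``slope_per_cm`` its linear change per cm of
    added diameter. The defaults are package configuration (declared
    assumptions, see the methods note), with signs fixed by the k-edge
    physics: soft spectra gain enhancement with size, hard spectra lose it.
    """

    base: Mapping[str, float] = field(
        default_factory=lambda: {"70": 44.0, "80": 40.0, "100": 34.0, "140": 24.0, "150Sn": 16.0}
    )
    slope_per_cm: Mapping[str, float] = field(
        default_factory=lambda: {"70": 0.20, "80": 0.15, "100": -0.12, "140": -0.15, "150Sn": -0.12}
    )
    reference_diameter_cm: float = 10.0

    def enhancement(self, spectrum: str, diameter_cm: float) -> float:
        if spectrum not in self.base:
            raise ConfigurationError(f"no enhancement configured for spectrum {spectrum!r}")
        return self.base[spectrum] + self.slope_per_cm[spectrum] * (
            diameter_cm - self.reference_diameter_cm
        )


DEFAULT_ENHANCEMENT = EnhancementConfig()
DEFAULT_NOISE = NoiseModel()


def enhancement_model(
    voltage_pair: str,
    diameter_cm: float,
    config: EnhancementConfig = DEFAULT_ENHANCEMENT,
) -> EnhancementVector:
    """Holmium enhancement vector (e_low, e_high) for a pair and object size.

    This is the generator's ground-truth material signature; the calibration
    module recovers it from simulated scans.
    """
    low, high = spectra_of(voltage_pair)
    d = float(diameter_cm)
    if not (min(calibration_diameters()) <= d <= max(calibration_diameters())):
        raise ConfigurationError(
            f"diameter {d} cm outside the calibrated range {calibration_diameters()}"
        )
    e_low = config.enhancement(low, d)
    e_high = config.enhancement(high, d)
    if e_low == e_high:
        raise ConfigurationError("configured enhancement has no spectral separation")
    return EnhancementVector(
        material="holmium", e_low=e_low, e_high=e_high, voltage_pair=voltage_pair, diameter_cm=d
    )


# ---------------------------------------------------------------------------
# rasterization helpers


def _grid_shape(extent_yx_mm: tuple[float, float], spec: AcquisitionSpec, margin_mm: float = 10.0):
    _, sy, sx = spec.voxel_spacing
    ny = int(np.ceil((extent_yx_mm[0] + 2 * margin_mm) / sy))
    nx = int(np.ceil((extent_yx_mm[1] + 2 * margin_mm) / sx))
    return (spec.slice_count, ny, nx)


def _rasterize(layout: PhantomLayout, shape, spacing):
    """Center-point rasterization of a layout.

    Returns (concentration, material_mask, deposit_labels). Voxels are
    assigned by containment of their centre point; no subsampling.
    """
    z, y, x = world_axes(shape, spacing)
    by, bx = layout.body_semi_axes
    body = (y[:, None] / by) ** 2 + (x[None, :] / bx) ** 2 <= 1.0
    body3 = np.broadcast_to(body, shape)

    conc = np.zeros(shape, dtype=float)
    material = np.where(body3, 1, 0).astype(np.uint8)
    labels = np.zeros(shape, dtype=np.int32)
    for k, ins in enumerate(layout.inserts, start=1):
        cz, cy, cx = ins.center
        if ins.shape == "cylinder":
            in_plane = (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2 <= ins.size[0] ** 2
            mask = np.broadcast_to(in_plane, shape)
        else:
            az, ay, ax = ins.size
            mask = (
                ((z[:, None, None] - cz) / az) ** 2
                + ((y[None, :, None] - cy) / ay) ** 2
                + ((x[None, None, :] - cx) / ax) ** 2
            ) <= 1.0
        if not mask.any():
            raise GeometryError(f"insert {k} rasterizes to zero voxels at this spacing")
        labels[mask] = k
        conc[mask] = ins.concentration
        if ins.concentration > 0:
            material[mask] = 2
    if layout.background_material == "air":
        material[~body3] = 0
    return conc, material, labels


def _forward(
    conc: np.ndarray,
    material: np.ndarray,
    vector: EnhancementVector,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless HU pair from concentration and material class."""
    base = np.where(material == 0, AIR_HU, WATER_HU)
    low = base + conc * vector.e_low
    high = base + conc * vector.e_high
    return low, high


def _add_noise(
    low: np.ndarray,
    high: np.ndarray,
    noise: NoiseModel,
    dose_mas: tuple[float, float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    sig = noise.sigma(dose_mas)
    rng = np.random.default_rng(seed)
    if sig[0] > 0 or sig[1] > 0:
        n1 = rng.standard_normal(low.shape)
        n2 = rng.standard_normal(low.shape)
        rho = noise.correlation
        low = low + sig[0] * n1
        high = high + sig[1] * (rho * n1 + np.sqrt(1.0 - rho**2) * n2)
    return np.maximum(low, HU_FLOOR), np.maximum(high, HU_FLOOR), sig


def _simulate(
    layout: PhantomLayout,
    spec: AcquisitionSpec,
    seed: int,
    noise: NoiseModel,
    enhancement: EnhancementConfig,
    effective_diameter_cm: float,
    dose_context: str,
) -> tuple[ImagePair, GroundTruth]:
    extent = (2 * layout.body_semi_axes[0], 2 * layout.body_semi_axes[1])
    shape = _grid_shape(extent, spec)
    conc, material, labels = _rasterize(layout, shape, spec.voxel_spacing)
    vector = enhancement_model(spec.voltage_pair, effective_diameter_cm, enhancement)
    low, high = _forward(conc, material, vector)
    low, high, sig = _add_noise(low, high, noise, spec.resolve_tube_current(dose_context), seed)

    vv = float(np.prod(spec.voxel_spacing)) / 1000.0
    masses = {
        int(k): float(conc[labels == k].sum() * vv) for k in np.unique(labels) if k > 0
    }
    truth = GroundTruth(
        concentration=conc,
        material_mask=material,
        deposit_labels=labels,
        masses_mg=masses,
        layout=layout,
        voxel_spacing=spec.voxel_spacing,
    )
    pair = ImagePair(low=low, high=high, acquisition=spec, seed=seed, noise=noise, noise_sigma=sig)
    return pair, truth


# ---------------------------------------------------------------------------
# phantom builders


def make_calibration_phantom(
    spec: AcquisitionSpec | None = None,
    reference_concentration: float = REFERENCE_CONCENTRATION,
    seed: int = 0,
    *,
    noise: NoiseModel = DEFAULT_NOISE,
    enhancement: EnhancementConfig = DEFAULT_ENHANCEMENT,
) -> tuple[ImagePair, GroundTruth]:
    """Spectral-calibration phantom scan.

    A water-equivalent cylinder (10 cm wide by default; extension rings give
    15-35 cm) holds two 2-cm syringes: the centric one with holmium at the
    reference concentration (default 10.5 mg/mL), the 3-cm-offset one with
    pure water as the HU reference. Enhancement follows the phantom's outer
    diameter.
    """
    if spec is None:
        spec = AcquisitionSpec(phantom_diameter=10.0)
    if reference_concentration <= 0:
        raise ConfigurationError("reference_concentration must be > 0")
    if spec.phantom_diameter == "animal":
        raise ConfigurationError("calibration phantom requires a numeric diameter")
    d_mm = float(spec.phantom_diameter) * 10.0
    if d_mm / 2.0 < 30.0 + 10.0:  # offset syringe at 3 cm + 1 cm radius must fit
        raise GeometryError("phantom diameter too small for the two-syringe layout")
    layout = PhantomLayout(
        background_material="air",
        body_semi_axes=(d_mm / 2.0, d_mm / 2.0),
        inserts=(
            Insert("cylinder", (0.0, 0.0, 0.0), (10.0,), reference_concentration),
            Insert("cylinder", (0.0, 0.0, 30.0), (10.0,), 0.0),
        ),
    )
    return _simulate(
        layout, spec, seed, noise, enhancement, float(spec.phantom_diameter), "calibration"
    )


def make_dilution_phantom(
    concentrations: Sequence[float],
    spec: AcquisitionSpec | None = None,
    dose_mode: str | None = None,
    seed: int = 0,
    *,
    insert_radius_mm: float = 7.5,
    ring_radius_mm: float = 50.0,
    noise: NoiseModel = DEFAULT_NOISE,
    enhancement: EnhancementConfig = DEFAULT_ENHANCEMENT,
) -> tuple[ImagePair, GroundTruth]:
    """Serial-dilution phantom: inserts equiangular, 5 cm off-centre, 20 cm body.

    ``concentrations`` may hold up to 8 values (the physical series was
    scanned in two groups); an empty list yields a background-only water
    phantom. ``dose_mode`` overrides the spec's dose setting.
    """
    if spec is None:
        spec = AcquisitionSpec(phantom_diameter=20.0)
    if dose_mode is not None and dose_mode != spec.dose_mode:
        spec = AcquisitionSpec(
            voltage_pair=spec.voltage_pair,
            dose_mode=dose_mode,
            phantom_diameter=spec.phantom_diameter,
            tube_current=spec.tube_current,
            voxel_spacing=spec.voxel_spacing,
            slice_count=spec.slice_count,
        )
    concentrations = [float(c) for c in concentrations]
    if any(c < 0 for c in concentrations):
        raise ConfigurationError("concentrations must be >= 0")
    n = len(concentrations)
    if n > 8:
        raise GeometryError("at most 8 inserts fit the equiangular ring layout")
    inserts = []
    for i, c in enumerate(concentrations):
        theta = 2.0 * np.pi * i / n
        cy = ring_radius_mm * np.sin(theta)
        cx = ring_radius_mm * np.cos(theta)
        inserts.append(Insert("cylinder", (0.0, float(cy), float(cx)), (insert_radius_mm,), c))
    if n > 1:
        chord = 2.0 * ring_radius_mm * np.sin(np.pi / n)
        if chord < 2.0 * insert_radius_mm:
            raise GeometryError("more inserts than non-overlapping angular slots at this radius")
    d_mm = float(spec.phantom_diameter) * 10.0
    layout = PhantomLayout(
        background_material="air",
        body_semi_axes=(d_mm / 2.0, d_mm / 2.0),
        inserts=tuple(inserts),
    )
    return _simulate(
        layout, spec, seed, noise, enhancement, float(spec.phantom_diameter), "quantification"
    )


@dataclass(frozen=True)
class Deposit:
    """A focal holmium deposit of known total mass."""

    mass_mg: float
    center: tuple[float, float, float]  # (z, y, x) mm
    volume_ml: float

    def __post_init__(self) -> None:
        if self.mass_mg <= 0 or self.volume_ml <= 0:
            raise ConfigurationError("deposit mass and volume must be > 0")

    @property
    def concentration(self) -> float:
        return self.mass_mg / self.volume_ml

    @property
    def radius_mm(self) -> float:
        return float((3.0 * self.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def make_animal_phantom(
    deposits: Sequence[Deposit],
    spec: AcquisitionSpec | None = None,
    seed: int = 0,
    *,
    body_semi_axes_mm: tuple[float, float] = (70.0, 100.0),
    noise: NoiseModel = DEFAULT_NOISE,
    enhancement: EnhancementConfig = DEFAULT_ENHANCEMENT,
) -> tuple[ImagePair, GroundTruth]:
    """Elliptical animal-like phantom with focal holmium deposits.

    The default outline (70 x 100 mm semi-axes, axis ratio 0.7) has a
    water-equivalent diameter of ~16.7 cm, inside the 15-20-cm range typical
    of a rabbit cadaver. Each deposit is an ellipsoid (spherical by default)
    whose rasterized concentration is normalized so its voxel-sum mass equals
    the requested injected mass exactly; an empty deposit list yields a
    deposit-free body.
    """
    if spec is None:
        spec = AcquisitionSpec(phantom_diameter="animal")
    inserts = []
    for dep in deposits:
        r = dep.radius_mm
        inserts.append(
            Insert("ellipsoid", dep.center, (r, r, r), dep.concentration)
        )
    layout = PhantomLayout(
        background_material="air",
        body_semi_axes=body_semi_axes_mm,
        inserts=tuple(inserts),
    )
    wed = layout.water_equivalent_diameter_cm
    pair, truth = _simulate(layout, spec, seed, noise, enhancement, wed, "quantification")
    if deposits:
        # renormalize each deposit so voxel-sum mass == requested mass exactly
        vv = truth.voxel_volume_ml
        conc = truth.concentration
        vector = enhancement_model(spec.voltage_pair, wed, enhancement)
        for k, dep in enumerate(deposits, start=1):
            sel = truth.deposit_labels == k
            raster_mass = float(conc[sel].sum() * vv)
            scale = dep.mass_mg / raster_mass
            delta = conc[sel] * (scale - 1.0)
            pair.low[sel] += delta * vector.e_low
            pair.high[sel] += delta * vector.e_high
            conc[sel] *= scale
            truth.masses_mg[k] = float(conc[sel].sum() * vv)
    return pair, truth
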