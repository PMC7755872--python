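"""Image-based three-material decomposition of dual-energy HU pairs.

Each voxel's measured HU pair ``P = (P_low, P_high)`` is expressed as a
mixture of three base materials — air at (-1000, -1000) HU, water at (0, 0)
HU, and holmium with calibrated enhancement vector ``e = (e_low, e_high)``:

    P = f_air * A + f_water * W + c * e,      f_air + f_water = 1

With two measurements and three materials the system is closed by volume
conservation of the air/water mixture; holmium enters as an additive
enhancement at concentration ``c`` (mg/mL). Substituting
``f_water = 1 - f_air`` gives an exact 2x2 linear solve per voxel:

    P - W = f_air * (A - W) + c * e

The solve inverts the noiseless forward model exactly; any third material in
the scene is, by construction, expressed as a linear combination of the two
base directions. The companion VNC (virtual non-contrast) image removes the
holmium enhancement: ``VNC = P - c * e``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AIR_HU, WATER_HU, EnhancementVector, ImagePair
from .errors import DegenerateSpectraError, RegistrationError

#: Minimum |e_low - e_high| (HU per mg/mL) for a usable holmium vector.
SEPARATION_FLOOR = 1.0


@dataclass(frozen=True)
class MaterialBasis:
    """Air/water/holmium basis of the decomposition."""

    holmium: EnhancementVector
    air_hu: tuple[float, float] = (AIR_HU, AIR_HU)
    water_hu: tuple[float, float] = (WATER_HU, WATER_HU)
    separation_floor: float = SEPARATION_FLOOR
    max_condition: float = 1e8

    def __post_init__(self) -> None:
        if self.holmium.separation <= self.separation_floor:
            raise DegenerateSpectraError(
                f"spectral separation {self.holmium.separation:.3g} HU/(mg/mL) is at or "
                f"below the floor of {self.separation_floor}; decomposition would be "
                "ill-conditioned"
            )
        m = self.matrix()
        if abs(np.linalg.det(m)) < 1e-12:
            raise DegenerateSpectraError("holmium vector is parallel to the water-air direction")
        if np.linalg.cond(m) > self.max_condition:
            raise DegenerateSpectraError("basis matrix condition number exceeds the cap")

    def matrix(self) -> np.ndarray:
        """Columns: (air - water) direction and the holmium vector."""
        a = np.subtract(self.air_hu, self.water_hu)
        e = self.holmium.as_array()
        return np.column_stack([a, e])

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix())

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix()))


def _solve(basis_inv: np.ndarray, p_low, p_high, water_hu):
    """Shared scalar/array solve; identical op order keeps the vectorized
    path bit-exact with the voxel loop."""
    dl = p_low - water_hu[0]
    dh = p_high - water_hu[1]
    f_air = basis_inv[0, 0] * dl + basis_inv[0, 1] * dh
    conc = basis_inv[1, 0] * dl + basis_inv[1, 1] * dh
    return conc, f_air


def decompose_voxel(hu_pair, basis: MaterialBasis):
    """Decompose one HU pair into (concentration mg/mL, f_air, f_water)."""
    conc, f_air = _solve(basis.inverse(), float(hu_pair[0]), float(hu_pair[1]), basis.water_hu)
    return float(conc), float(f_air), float(1.0 - f_air)


def vnc_voxel(hu_pair, concentration: float, basis: MaterialBasis):
    """Virtually remove the holmium enhancement from one HU pair."""
    e = basis.holmium
    return (
        float(hu_pair[0]) - concentration * e.e_low,
        float(hu_pair[1]) - concentration * e.e_high,
    )


@dataclass
class ConcentrationMap:
    """Voxelwise holmium concentration plus paired VNC volumes."""

    concentration: np.ndarray  # mg/mL
    vnc_low: np.ndarray  # HU
    vnc_high: np.ndarray  # HU
    vnc_mixed: np.ndarray  # HU, weighted mix of the two VNC volumes
    basis: MaterialBasis
    voxel_spacing: tuple[float, float, float]
    clip_negative: bool = False
    vnc_mix_weight: float = 0.5

    @property
    def shape(self):
        return self.concentration.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing)) / 1000.0


@dataclass(frozen=True)
class DecompositionDiagnostics:
    """Quality-control record of one decomposition run."""

    condition_number: float
    fraction_clipped: float
    fraction_air_outside_unit: float  # f_air outside [0, 1]

    def __post_init__(self) -> None:
        for f in (self.fraction_clipped, self.fraction_air_outside_unit):
            if not 0.0 <= f <= 1.0:
                raise ValueError("diagnostic fractions must lie in [0, 1]")


def decompose_image(
    pair: ImagePair,
    basis: MaterialBasis,
    clip_negative: bool = False,
    vnc_mix_weight: float = 0.5,
) -> tuple[ConcentrationMap, DecompositionDiagnostics]:
    """Vectorized per-voxel decomposition of a co-registered image pair.

    VNC volumes are computed from the *unclipped* concentration; with
    ``clip_negative`` the emitted map is floored at 0 afterwards (noise-driven
    negative concentrations are preserved by default so ROI means stay
    unbiased).
    """
    if pair.low.shape != pair.high.shape:
        raise RegistrationError("image pair volumes are not co-registered")
    binv = basis.inverse()
    conc, f_air = _solve(binv, pair.low, pair.high, basis.water_hu)
    e = basis.holmium
    vnc_low = pair.low - conc * e.e_low
    vnc_high = pair.high - conc * e.e_high
    w = vnc_mix_weight
    vnc_mixed = w * vnc_low + (1.0 - w) * vnc_high
    n = conc.size
    frac_clipped = float(np.count_nonzero(conc < 0)) / n if clip_negative else 0.0
    frac_outside = float(np.count_nonzero((f_air < 0) | (f_air > 1))) / n
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    cmap = ConcentrationMap(
        concentration=conc,
        vnc_low=vnc_low,
        vnc_high=vnc_high,
        vnc_mixed=vnc_mixed,
        basis=basis,
        voxel_spacing=pair.spacing,
        clip_negative=clip_negative,
        vnc_mix_weight=w,
    )
    diag = DecompositionDiagnostics(
        condition_number=basis.condition_number,
        fraction_clipped=frac_clipped,
        fraction_air_outside_unit=frac_outside,
    )
    return cmap, diag


def concentration_noise_sd(
    sigma_low: float, sigma_high: float, basis: MaterialBasis, correlation: float = 0.0
) -> float:
    """Closed-form per-voxel sd of the concentration estimate.

    Propagates the two image-noise standard deviations through the second row
    of the inverse basis matrix (the concentration solve is linear in the HU
    pair).
    """
    binv = basis.inverse()
    a, b = binv[1, 0], binv[1, 1]
    var = (a * sigma_low) ** 2 + (b * sigma_high) ** 2 + 2 * a * b * correlation * sigma_low * sigma_high
    return float(np.sqrt(var))
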