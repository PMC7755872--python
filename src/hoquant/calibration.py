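"""Spectral calibration: enhancement-vector estimation and the size/voltage table.

A calibration scan images a known holmium concentration (reference syringe)
next to a pure-water syringe. The water ROI anchors the HU origin, so the
enhancement vector is the water-referenced two-point calibration through the
origin:

    e = (mean_holmium - mean_water) / C_reference      (per spectrum)

Vectors are assembled into a :class:`CalibrationTable` keyed by
(tube-voltage pair, phantom diameter); lookups of missing keys fail loudly,
and linear interpolation between bracketing diameters is available only
through the dedicated flag (object sizes between calibrated rings, e.g. an
animal's water-equivalent diameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import EnhancementVector, ImagePair, RoiSpec
from .errors import (
    CalibrationLookupError,
    ConfigurationError,
    DegenerateSpectraError,
    ProvenanceError,
)
from .decompose import SEPARATION_FLOOR

#: Default ROIs of the two calibration syringes (2-cm diameter, 2-mm erosion).
HOLMIUM_ROI = RoiSpec(shape="cylinder", center=(0.0, 0.0, 0.0), radius=10.0)
WATER_ROI = RoiSpec(shape="cylinder", center=(0.0, 0.0, 30.0), radius=10.0)


def extract_roi_mean(pair: ImagePair, roi: RoiSpec):
    """(mean_low, mean_high, sd_low, sd_high, n) over the eroded ROI.

    Statistics are computed over the identical voxel set in both volumes.
    """
    return pair.roi_stats(roi)


def fit_enhancement_vector(
    holmium_roi_means: tuple[float, float],
    water_roi_means: tuple[float, float],
    reference_concentration: float,
    *,
    voltage_pair: str = "",
    diameter_cm: float = float("nan"),
    separation_floor: float = SEPARATION_FLOOR,
) -> EnhancementVector:
    """Water-referenced two-point calibration of the holmium vector."""
    if reference_concentration <= 0:
        raise ConfigurationError("reference_concentration must be > 0")
    e_low = (holmium_roi_means[0] - water_roi_means[0]) / reference_concentration
    e_high = (holmium_roi_means[1] - water_roi_means[1]) / reference_concentration
    if abs(e_low - e_high) <= separation_floor:
        raise DegenerateSpectraError(
            f"fitted spectral separation {abs(e_low - e_high):.3g} HU/(mg/mL) at or below "
            f"floor {separation_floor}; calibration scan is degenerate"
        )
    return EnhancementVector(
        material="holmium",
        e_low=float(e_low),
        e_high=float(e_high),
        voltage_pair=voltage_pair,
        diameter_cm=float(diameter_cm),
        reference_concentration=reference_concentration,
    )


def calibrate_scan(
    pair: ImagePair,
    reference_concentration: float,
    holmium_roi: RoiSpec = HOLMIUM_ROI,
    water_roi: RoiSpec = WATER_ROI,
) -> EnhancementVector:
    """Fit the holmium vector from one calibration-phantom image pair."""
    ho = extract_roi_mean(pair, holmium_roi)
    wa = extract_roi_mean(pair, water_roi)
    spec = pair.acquisition
    return fit_enhancement_vector(
        (ho[0], ho[1]),
        (wa[0], wa[1]),
        reference_concentration,
        voltage_pair=spec.voltage_pair,
        diameter_cm=float(spec.phantom_diameter),
    )


@dataclass
class CalibrationTable:
    """Enhancement vectors indexed by (tube-voltage pair, diameter in cm)."""

    entries: dict[tuple[str, float], EnhancementVector] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)

    def add(self, vector: EnhancementVector) -> None:
        key = (vector.voltage_pair, float(vector.diameter_cm))
        if key in self.entries:
            raise ProvenanceError(f"duplicate calibration entry for {key}")
        self.entries[key] = vector

    def __len__(self) -> int:
        return len(self.entries)

    def diameters_for(self, voltage_pair: str) -> list[float]:
        return sorted(d for (vp, d) in self.entries if vp == voltage_pair)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "provenance": self.provenance,
            "entries": [
                {
                    "voltage_pair": v.voltage_pair,
                    "diameter_cm": v.diameter_cm,
                    "material": v.material,
                    "e_low": v.e_low,
                    "e_high": v.e_high,
                    "reference_concentration": v.reference_concentration,
                }
                for _, v in sorted(self.entries.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationTable":
        table = cls(provenance=dict(d.get("provenance", {})))
        for e in d["entries"]:
            table.add(
                EnhancementVector(
                    material=e.get("material", "holmium"),
                    e_low=e["e_low"],
                    e_high=e["e_high"],
                    voltage_pair=e["voltage_pair"],
                    diameter_cm=e["diameter_cm"],
                    reference_concentration=e.get("reference_concentration"),
                )
            )
        return table


def build_calibration_table(
    scans: Iterable[tuple[ImagePair, float]],
    holmium_roi: RoiSpec = HOLMIUM_ROI,
    water_roi: RoiSpec = WATER_ROI,
) -> CalibrationTable:
    """Fit one vector per calibration scan and assemble the table.

    ``scans`` yields (image pair, reference concentration); voltage pair and
    diameter come from each pair's acquisition metadata. Duplicate
    (pair, diameter) keys are rejected.
    """
    table = CalibrationTable()
    seeds = []
    for pair, ref in scans:
        table.add(calibrate_scan(pair, ref, holmium_roi, water_roi))
        seeds.append(pair.seed)
    table.provenance["scan_seeds"] = seeds
    return table


def lookup_vector(
    table: CalibrationTable,
    voltage_pair: str,
    diameter_cm: float,
    allow_interpolation: bool = False,
) -> EnhancementVector:
    """Exact-key lookup, optionally with linear interpolation across diameters.

    Interpolation is componentwise linear between the two calibrated
    diameters bracketing the request, at the same voltage pair; requests
    outside the calibrated diameter range are refused (no extrapolation).
    """
    if not table.entries:
        raise CalibrationLookupError("calibration table is empty")
    d = float(diameter_cm)
    key = (voltage_pair, d)
    if key in table.entries:
        return table.entries[key]
    if not allow_interpolation:
        raise CalibrationLookupError(
            f"no calibration entry for {key}; enable interpolation or calibrate this size"
        )
    ds = table.diameters_for(voltage_pair)
    if not ds:
        raise CalibrationLookupError(f"no entries for voltage pair {voltage_pair!r}")
    if not ds[0] <= d <= ds[-1]:
        raise CalibrationLookupError(
            f"diameter {d} cm outside calibrated range [{ds[0]}, {ds[-1]}] for {voltage_pair}"
        )
    lo = max(x for x in ds if x <= d)
    hi = min(x for x in ds if x >= d)
    vlo = table.entries[(voltage_pair, lo)]
    vhi = table.entries[(voltage_pair, hi)]
    t = 0.0 if hi == lo else (d - lo) / (hi - lo)
    return EnhancementVector(
        material=vlo.material,
        e_low=(1 - t) * vlo.e_low + t * vhi.e_low,
        e_high=(1 - t) * vlo.e_high + t * vhi.e_high,
        voltage_pair=voltage_pair,
        diameter_cm=d,
        reference_concentration=vlo.reference_concentration,
    )
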