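"""On-disk formats: NIfTI volume pairs with JSON sidecars, an NPZ dialect,
calibration tables and ground truth.

Arrays are stored in (slice, row, column) order; the NIfTI affine is the
diagonal spacing matrix in the same order with the origin at the volume
centre (a pipeline dialect, not a scanner geometry).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .calibration import CalibrationTable
from .core import AcquisitionSpec, GroundTruth, ImagePair, NoiseModel


def _affine(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def _sidecar(pair: ImagePair) -> dict:
    return {
        "schema_version": 1,
        "acquisition": dataclasses.asdict(pair.acquisition),
        "seed": pair.seed,
        "noise": dataclasses.asdict(pair.noise),
        "noise_sigma": list(pair.noise_sigma),
    }


def _pair_from_sidecar(low: np.ndarray, high: np.ndarray, meta: dict) -> ImagePair:
    acq = meta["acquisition"]
    if acq.get("tube_current") is not None:
        acq["tube_current"] = tuple(acq["tube_current"])
    acq["voxel_spacing"] = tuple(acq["voxel_spacing"])
    noise = meta.get("noise", {})
    if "sigma_ref" in noise:
        noise["sigma_ref"] = tuple(noise["sigma_ref"])
    return ImagePair(
        low=low,
        high=high,
        acquisition=AcquisitionSpec(**acq),
        seed=meta.get("seed"),
        noise=NoiseModel(**noise) if noise else NoiseModel(),
        noise_sigma=tuple(meta.get("noise_sigma", (0.0, 0.0))),
    )


def save_image_pair(pair: ImagePair, directory: str | Path, stem: str) -> dict[str, Path]:
    """Write ``{stem}_low.nii.gz``, ``{stem}_high.nii.gz`` and ``{stem}.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(pair.spacing)
    paths = {}
    for name, vol in (("low", pair.low), ("high", pair.high)):
        p = directory / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), p)
        paths[name] = p
    sidecar = directory / f"{stem}.json"
    sidecar.write_text(json.dumps(_sidecar(pair), indent=2, sort_keys=True))
    paths["sidecar"] = sidecar
    return paths


def load_image_pair(directory: str | Path, stem: str) -> ImagePair:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    low = np.asarray(nib.load(directory / f"{stem}_low.nii.gz").dataobj, dtype=float)
    high = np.asarray(nib.load(directory / f"{stem}_high.nii.gz").dataobj, dtype=float)
    return _pair_from_sidecar(low, high, meta)


def save_image_pair_npz(pair: ImagePair, path: str | Path) -> Path:
    """Single-archive dialect with the same keys as the NIfTI sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, low=pair.low, high=pair.high, sidecar=json.dumps(_sidecar(pair), sort_keys=True)
    )
    return path


def load_image_pair_npz(path: str | Path) -> ImagePair:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["sidecar"]))
        return _pair_from_sidecar(np.asarray(z["low"], float), np.asarray(z["high"], float), meta)


def save_ground_truth(truth: GroundTruth, directory: str | Path, stem: str) -> dict[str, Path]:
    """Concentration NIfTI plus a JSON deposit/mass table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(truth.voxel_spacing)
    conc_path = directory / f"{stem}_truth.nii.gz"
    nib.save(nib.Nifti1Image(truth.concentration.astype(np.float32), aff), conc_path)
    labels_path = directory / f"{stem}_labels.nii.gz"
    nib.save(nib.Nifti1Image(truth.deposit_labels.astype(np.int16), aff), labels_path)
    table = {
        "schema_version": 1,
        "voxel_spacing": list(truth.voxel_spacing),
        "masses_mg": {str(k): v for k, v in truth.masses_mg.items()},
    }
    json_path = directory / f"{stem}_truth.json"
    json_path.write_text(json.dumps(table, indent=2, sort_keys=True))
    return {"concentration": conc_path, "labels": labels_path, "table": json_path}


def save_calibration_table(table: CalibrationTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(table.to_dict(), indent=2, sort_keys=True))
    return path


def load_calibration_table(path: str | Path) -> CalibrationTable:
    return CalibrationTable.from_dict(json.loads(Path(path).read_text()))
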