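"""File input/output: NIfTI volumes, realignment TSVs, configs, sidecars.

Volumes are written as NIfTI-1 through nibabel with the voxel size
recorded in a diagonal affine.  Realignment parameters travel as
six-column TSV files with the conventional header (``trans_x`` ...
``rot_z``).  Run configurations are plain JSON or YAML documents whose
keys mirror :class:`~alffpipe.simulate.SimulationConfig`; map and
statistic metadata live in JSON sidecars next to the volumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .simulate import SimulationConfig, SubjectDataset, TISSUES
from .spectral import FluctuationMap

__all__ = [
    "RP_COLUMNS",
    "save_volume",
    "load_volume",
    "save_realignment_params",
    "load_realignment_params",
    "load_config",
    "save_config",
    "save_fluctuation_map",
    "save_dataset",
]

RP_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _affine(voxel_size_mm) -> np.ndarray:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    return affine


def save_volume(path: str | Path, values: np.ndarray, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    """Write a 3-D or 4-D array as NIfTI-1 with the voxel size in the affine."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns the data and the voxel size in mm."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), zooms


def save_realignment_params(path: str | Path, rp: np.ndarray) -> None:
    rp = np.asarray(rp, dtype=float)
    if rp.ndim != 2 or rp.shape[1] != 6:
        raise ValueError("realignment parameters must be an N x 6 matrix")
    pd.DataFrame(rp, columns=RP_COLUMNS).to_csv(path, sep="\t", index=False)


def load_realignment_params(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"realignment TSV missing columns {missing}")
    return df[RP_COLUMNS].to_numpy(dtype=float)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a simulation config from a JSON or YAML document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(payload) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("grid_dims", "voxel_size_mm", "lff_band", "physio_freqs", "bias_field_range"):
        if key in payload and isinstance(payload[key], list):
            payload[key] = tuple(payload[key])
    return SimulationConfig(**payload)


def save_config(path: str | Path, config: SimulationConfig) -> None:
    payload = dataclasses.asdict(config)
    for key, value in payload.items():
        if isinstance(value, tuple):
            payload[key] = list(value)
    text = (
        json.dumps(payload, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(payload, sort_keys=False)
    )
    Path(path).write_text(text)


def save_fluctuation_map(
    path: str | Path, fmap: FluctuationMap, voxel_size_mm=(3.0, 3.0, 3.0)
) -> None:
    """Write a fluctuation map plus a JSON sidecar with its provenance."""
    path = Path(path)
    save_volume(path, fmap.values, voxel_size_mm)
    sidecar = {
        "measure": fmap.measure,
        "band_hz": [fmap.band.low, fmap.band.high],
        "standardised": fmap.standardised,
        "smoothing_fwhm_mm": fmap.smoothing_fwhm_mm,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def save_dataset(directory: str | Path, dataset: SubjectDataset, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    """Serialise one synthetic session: volumes, RP TSV, ground truth bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(directory / "bold.nii", dataset.bold, voxel_size_mm)
    for tissue in TISSUES:
        save_volume(
            directory / f"mask_{tissue}.nii",
            dataset.masks[tissue].astype(np.float64),
            voxel_size_mm,
        )
    save_volume(directory / "bias_field.nii", dataset.bias_field, voxel_size_mm)
    save_realignment_params(directory / "realignment.tsv", dataset.realignment_params)
    save_volume(
        directory / "true_amplitude_map.nii",
        dataset.ground_truth.amplitude_map,
        voxel_size_mm,
    )
    truth = dataset.ground_truth
    components = pd.DataFrame(
        {
            "drift": truth.drift,
            "slow_drift": truth.slow_drift,
            "motion_signal": truth.motion_signal,
            **{f"physio_{j}": truth.physio[:, j] for j in range(truth.physio.shape[1])},
        }
    )
    components.to_csv(directory / "ground_truth_timecourses.tsv", sep="\t", index=False)
    sidecar = {
        "subject_index": dataset.subject_index,
        "session_index": dataset.session_index,
        "tr_seconds": dataset.tr_seconds,
        "drift_coeffs": truth.drift_coeffs.tolist(),
        "subject_drift_coeffs": truth.subject_drift_coeffs.tolist(),
    }
    (directory / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
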