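"""File I/O: NIfTI volumes, TSV tables, YAML configs and JSON provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthetic import ROI_NAMES, ActivationTruth, PhantomAtlas, VolumeSeries

__all__ = [
    "save_series",
    "load_series",
    "save_atlas",
    "load_atlas",
    "save_mask",
    "load_mask",
    "write_tsv",
    "read_tsv",
    "write_json",
    "file_sha256",
]


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def save_series(series: VolumeSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size))
    img.header.set_zooms((series.voxel_size,) * 3 + (series.tr,))
    nib.save(img, str(path))
    return path


def load_series(path: str | Path) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    return VolumeSeries(data=data, tr=float(zooms[3]), voxel_size=float(zooms[0]))


def save_atlas(atlas: PhantomAtlas, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size))
    nib.save(img, str(path))
    return path


def load_atlas(path: str | Path) -> PhantomAtlas:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int16)
    voxel = float(img.header.get_zooms()[0])
    return PhantomAtlas(labels=labels, voxel_size=voxel, roi_names=dict(ROI_NAMES))


def save_mask(mask: np.ndarray, voxel_size: float, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(bool)


def save_truth(truth: ActivationTruth, voxel_size: float, mask_path: Path, amp_path: Path) -> None:
    save_mask(truth.mask, voxel_size, mask_path)
    img = nib.Nifti1Image(truth.amplitude.astype(np.float32), _affine(voxel_size))
    nib.save(img, str(amp_path))


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
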