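"""NIfTI I/O for volumes and masks, plus CSV/JSON metric reports.

Volumes are stored as NIfTI-1 with the voxel spacing carried in the affine
(diagonal, RAS-aligned). Masks are written as unsigned 8-bit; any nonzero
value reads back as 1.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import BinaryMask, ScalarVolume, assert_same_grid  # noqa: F401

REPORT_COLUMNS = ["plan", "structure", "metric", "value", "units"]
DVH_COLUMNS = ["structure", "dose_Gy", "volume_percent"]


class VolumeFormatError(ValueError):
    """Raised for files that are not valid single 3-D volumes."""


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a single 3-D NIfTI volume; spacing is taken from the header in mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if not all(np.isfinite(z) and z > 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-finite or non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ScalarVolume(values=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a scalar volume as NIfTI-1 (float64)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "") -> BinaryMask:
    """Read a binary mask; any nonzero voxel becomes 1."""
    vol = read_volume(path)
    return BinaryMask(values=vol.values != 0, spacing=vol.spacing, origin=vol.origin,
                      label=label or Path(path).stem.replace(".nii", ""))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def write_report(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write a per-structure metric table as CSV plus a JSON twin.

    Expects rows keyed by (plan, structure, metric) with ``value`` and
    ``units`` columns; column order in the CSV is fixed.
    """
    path = Path(path)
    df = metrics.copy()
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col != "value" else np.nan
    df = df[REPORT_COLUMNS]
    df.to_csv(path, index=False)
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(df.to_dict(orient="records"), indent=1, default=float))


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dvh(dvh_table: pd.DataFrame, path: str | Path) -> None:
    """Write cumulative DVH curves as CSV (structure, dose_Gy, volume_percent)."""
    dvh_table[DVH_COLUMNS].to_csv(Path(path), index=False)
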