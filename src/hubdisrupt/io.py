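"""File formats: NIfTI images, motion traces, phenotype tables, reports.

NIfTI round-trips preserve data to float32 precision, the voxel size in the
header zooms, and the repetition time in the 4th zoom.  Motion traces are
6-column whitespace-delimited text; the column order (3 translations in mm,
then 3 rotations in radians) is fixed and written in the header comment of
every file this package produces.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BoldSeries

__all__ = [
    "write_nifti",
    "read_nifti",
    "bold_to_4d",
    "bold_from_4d",
    "write_bold_nifti",
    "read_bold_nifti",
    "write_motion",
    "read_motion",
    "write_phenotype",
    "read_phenotype",
]

MOTION_HEADER = (
    "# columns: trans_x_mm trans_y_mm trans_z_mm rot_pitch_rad rot_yaw_rad rot_roll_rad"
)
PHENOTYPE_COLUMNS = [
    "subject_id",
    "group",
    "side",
    "age",
    "gender",
    "fma_baseline",
    "fma_followup",
]
FMA_MAX = 66.0


def write_nifti(
    data: np.ndarray, path: str | Path, voxel_size: float = 6.0, tr: float | None = None
) -> None:
    """Write a 3-D or 4-D array as NIfTI with an isotropic diagonal affine."""
    data = np.asarray(data, dtype=np.float32)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = [voxel_size] * 3 + ([tr] if data.ndim == 4 and tr is not None else [])
    img.header.set_zooms(tuple(zooms) if len(zooms) > 3 else (voxel_size,) * 3)
    if data.ndim == 4 and tr is not None:
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, float, float | None]:
    """Read a NIfTI image; returns (data, voxel_size_mm, tr_seconds_or_None)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else None
    return np.asarray(img.dataobj, dtype=np.float64), float(zooms[0]), tr


def bold_to_4d(bold: BoldSeries) -> tuple[np.ndarray, np.ndarray]:
    """Scatter a BoldSeries onto its bounding grid; returns (4-D data, 3-D mask)."""
    coords = bold.voxel_coords
    shape = tuple(coords.max(axis=0) + 1)
    data = np.zeros(shape + (bold.n_volumes,), dtype=np.float64)
    mask = np.zeros(shape, dtype=bool)
    data[tuple(coords.T)] = bold.data
    mask[tuple(coords.T)] = True
    return data, mask


def bold_from_4d(
    data4d: np.ndarray, mask: np.ndarray, voxel_size: float, tr: float
) -> BoldSeries:
    """Extract the masked voxel time series from a 4-D grid."""
    data4d = np.asarray(data4d)
    mask = np.asarray(mask, dtype=bool)
    if data4d.shape[:3] != mask.shape:
        raise ValueError(
            f"BOLD grid {data4d.shape[:3]} does not match mask grid {mask.shape}"
        )
    coords = np.argwhere(mask)
    return BoldSeries(data4d[mask], coords, voxel_size, tr)


def write_bold_nifti(bold: BoldSeries, bold_path: str | Path, mask_path: str | Path) -> None:
    data, mask = bold_to_4d(bold)
    write_nifti(data, bold_path, bold.voxel_size, bold.tr)
    write_nifti(mask.astype(np.float32), mask_path, bold.voxel_size)


def read_bold_nifti(bold_path: str | Path, mask_path: str | Path) -> BoldSeries:
    data, voxel_size, tr = read_nifti(bold_path)
    mask, mask_vs, _ = read_nifti(mask_path)
    if data.shape[:3] != mask.shape:
        raise ValueError(
            f"BOLD grid {data.shape[:3]} does not match mask grid {mask.shape}"
        )
    return bold_from_4d(data, mask > 0.5, voxel_size, tr if tr else 1.0)


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    np.savetxt(path, motion, fmt="%.8f", header=MOTION_HEADER.lstrip("# "))


def read_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    return motion


def write_phenotype(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=[c for c in PHENOTYPE_COLUMNS if c in table])


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype CSV.

    Requires unique subject ids and motor scores within [0, 66]; missing
    follow-up scores are allowed (not every subject returns for follow-up).
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table is missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    for col in ("fma_baseline", "fma_followup"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > FMA_MAX)).any():
                raise ValueError(f"{col} outside [0, {FMA_MAX}]")
    return df


def subjects_to_phenotype(subjects) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "side": s.side,
            "age": round(s.age, 1),
            "gender": "M" if s.gender else "F",
            "fma_baseline": None if s.fma_baseline is None else round(s.fma_baseline, 2),
            "fma_followup": None if s.fma_followup is None else round(s.fma_followup, 2),
        }
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
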