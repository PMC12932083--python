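"""File I/O: NIfTI volumes, realignment tables, clinical TSVs.

All tabular output is tab-separated with a header row and '.' decimals;
volumes are NIfTI-1 via nibabel.  Round-trips preserve grids, affines
and tables losslessly (up to the fixed float format for TSV).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_motion",
    "write_motion",
    "read_clinical",
    "write_tsv",
    "read_tsv",
]

_SMOKING_COLUMNS = ("ftnd", "cpd", "duration", "onset_age", "pack_years")
_CLINICAL_COLUMNS = ("subject_id", "group", "age") + _SMOKING_COLUMNS

FLOAT_FORMAT = "%.10g"


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    return np.asarray(img.dataobj), img.affine


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_motion(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited T x 6 realignment-parameter file.

    Columns: three translations (mm) then three rotations (radians).
    """
    table = np.loadtxt(str(path), ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(
            f"motion file {path} has {table.shape[1]} columns, expected 6 "
            "(3 translations mm, 3 rotations rad)"
        )
    return table


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be T x 6")
    np.savetxt(str(path), motion, fmt="%.8f")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical covariate TSV.

    Every smoker row must carry complete smoking history (FTND,
    cigarettes/day, duration, onset age, pack-years); control rows must
    leave those fields empty.
    """
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"clinical table {path} lacks columns {missing_cols}")
    bad_groups = set(df["group"]) - {"smoker", "control"}
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)} in {path}")
    for _, row in df.iterrows():
        if row["group"] == "smoker":
            absent = [c for c in _SMOKING_COLUMNS if pd.isna(row[c])]
            if absent:
                raise ValueError(
                    f"smoker row {row['subject_id']!r} is missing {absent}"
                )
        else:
            present = [c for c in _SMOKING_COLUMNS if pd.notna(row[c])]
            if present:
                raise ValueError(
                    f"control row {row['subject_id']!r} carries smoking "
                    f"fields {present}"
                )
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with a fixed float format (reproducible bytes)."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
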