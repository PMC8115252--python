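"""Typed TSV tables keyed by subject identifier.

Tables use tab separation and BIDS-flavoured column names (``onset``,
``duration`` for events; ``trans_x .. rot_z`` for rigid motion).  The subject
identifier is an opaque string key and must be unique.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


class TableSchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(
    path: Union[str, Path],
    required: Sequence[str] = (),
    numeric: Sequence[str] = (),
    index: Optional[str] = None,
) -> pd.DataFrame:
    """Read a TSV with header; validate required and numeric columns.

    Parameters
    ----------
    required : column names that must be present.
    numeric : columns that must parse as numbers; a non-numeric cell raises
        :class:`TableSchemaError` naming the offending row and column.
    index : optional column (e.g. ``subject_id``) checked for uniqueness and
        kept as a string-typed column.
    """
    df = pd.read_csv(path, sep="\t", dtype={index: str} if index else None)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableSchemaError(
                f"{path}: non-numeric value in column {col!r} at row {row}"
            )
        df[col] = coerced
    if index is not None:
        if df[index].duplicated().any():
            dup = df[index][df[index].duplicated()].iloc[0]
            raise TableSchemaError(f"{path}: duplicate {index} {dup!r}")
    return df


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    return read_table(path, required=("onset", "duration"), numeric=("onset", "duration"))


def read_motion(path: Union[str, Path]) -> pd.DataFrame:
    df = read_table(path, required=MOTION_COLUMNS, numeric=MOTION_COLUMNS)
    return df[list(MOTION_COLUMNS)]


def motion_to_frame(motion: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    """Coerce a motion table to a (T, 6) float array (translations then rotations)."""
    if isinstance(motion, pd.DataFrame):
        cols = [c for c in MOTION_COLUMNS if c in motion.columns]
        arr = motion[cols].to_numpy(float) if len(cols) == 6 else motion.to_numpy(float)
    else:
        arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise TableSchemaError(f"motion table must be T x 6, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise TableSchemaError("motion table contains non-finite values")
    return arr
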