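"""Reading and writing treatment-record CSV tables.

Column names encode units (``bw_kg``, ``dmi_kg_d``, ``ch4_mj_d``, ...; see
:mod:`ch4meta.schema`); one row is one treatment mean; missing values are
empty cells.  Unknown columns are preserved as passthrough.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import schema
from .errors import ValidationError

__all__ = ["read_records", "write_records"]

_POSITIVE_COLUMNS = [
    c
    for c in schema.NUMERIC_COLUMNS
    if c not in ("fe_mj_d", "ue_mj_d")  # energy losses may legitimately be ~0
]


def read_records(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a treatment-record CSV.

    Raises
    ------
    ValidationError
        On a missing mandatory column, a malformed numeric cell (with its
        row and column) or a nonpositive quantity.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in schema.MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing mandatory column(s) {missing}")
    for col in schema.NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        try:
            # numpy's parser is correctly rounded, so write/read round-trips
            # are exact to the last ulp
            df[col] = df[col].astype(float)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad[0]) + 2  # header + 1-based
            raise ValidationError(
                f"{path.name}: malformed numeric cell in column {col!r}, file row {row}"
            ) from None
    for col in _POSITIVE_COLUMNS:
        if col not in df.columns:
            continue
        bad = df.index[df[col].notna() & (df[col] <= 0)]
        if len(bad):
            raise ValidationError(
                f"{path.name}: nonpositive value in column {col!r}, "
                f"file row {int(bad[0]) + 2}"
            )
    return df


def write_records(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a record table in the pipeline CSV schema (stable column order)."""
    known = [c for c in schema.ALL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in schema.ALL_COLUMNS]
    df[known + extra].to_csv(path, index=False)
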