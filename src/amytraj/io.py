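"""Visit-table CSV input/output.

The on-disk dialect is fixed: comma-separated, UTF-8, header row exactly the
canonical column order, missing values written as empty strings.  Reading is
strict by default (unknown columns rejected) and names the offending data row
on malformed numerics, so generator output and hand-edited files fail fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CLINICAL_MEASURES, VISIT_COLUMNS

__all__ = ["read_visits", "write_visits"]

_NUMERIC = ("age", "time_years", "suvr") + CLINICAL_MEASURES
_REQUIRED_NUMERIC = ("age", "time_years", "suvr")  # may not be missing


def write_visits(visits: pd.DataFrame, path: str) -> None:
    """Write a visit table in the canonical dialect (lossless round-trip)."""
    out = visits[list(VISIT_COLUMNS)]
    out.to_csv(path, index=False, na_rep="")


def read_visits(path: str, lax: bool = False) -> pd.DataFrame:
    """Read a visit-table CSV.

    ``lax=True`` tolerates (and drops) unknown columns; otherwise the header
    must match the canonical column set exactly.  Malformed numeric cells
    raise with the 1-based data row number.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    missing = [c for c in VISIT_COLUMNS if c not in cols]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    extra = [c for c in cols if c not in VISIT_COLUMNS]
    if extra and not lax:
        raise ValueError(
            f"unknown column(s): {extra}; pass lax=True to ignore them"
        )
    out = raw[list(VISIT_COLUMNS)].copy()
    for c in _NUMERIC:
        col = out[c].str.strip()
        converted = pd.to_numeric(col.replace("", np.nan), errors="coerce")
        bad = converted.isna() & (col != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(
                f"malformed numeric value {col.iloc[row - 1]!r} in column "
                f"{c!r} at data row {row}"
            )
        if c in _REQUIRED_NUMERIC and converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 1
            raise ValueError(f"missing required value in column {c!r} at data row {row}")
        out[c] = converted.astype(float)
    return out
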