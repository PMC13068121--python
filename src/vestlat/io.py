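"""Cohort CSV reading/writing with strict column validation.

The CSV contract is one row per subject with columns exactly::

    subject_id, ll, rl, la, ra, lp, rp,
    cvemp_left, cvemp_right, ovemp_left, ovemp_right,
    caloric_right_cold, caloric_right_warm, caloric_left_cold,
    caloric_left_warm, svv_1..svv_6, true_side

Empty cells are missing values; ``true_side`` is empty for controls.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .records import COLUMNS, RawRecord, frame_to_records, records_to_frame

__all__ = ["read_cohort", "write_cohort"]

logger = logging.getLogger("vestlat")


def read_cohort(path) -> list[RawRecord]:
    """Read and validate a cohort CSV; logs per-column missingness."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc

    got, want = list(df.columns), list(COLUMNS)
    missing = [c for c in want if c not in got]
    unknown = [c for c in got if c not in want]
    if missing or unknown:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if unknown:
            parts.append(f"unknown column(s) {unknown}")
        raise ParseError(f"{path}: " + "; ".join(parts))
    df = df[want]

    for col in want[1:]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row {row + 2}, column '{col}'"
            )
        df[col] = coerced

    dup = df["subject_id"].duplicated()
    if dup.any():
        raise ParseError(
            f"{path}: duplicate subject_id {df['subject_id'][dup].iloc[0]!r}"
        )

    side = df["true_side"].dropna()
    if not side.isin([-1, 1]).all():
        bad = side[~side.isin([-1, 1])].iloc[0]
        raise ParseError(f"{path}: true_side must be -1 or +1, got {bad!r}")

    miss = df[want[1:]].isna().mean() * 100
    logger.info(
        "read %d record(s) from %s; %% missing per column: %s",
        len(df),
        path,
        ", ".join(f"{c}={v:.1f}" for c, v in miss.items() if v > 0) or "none",
    )
    return frame_to_records(df)


def write_cohort(records: Sequence[RawRecord], path) -> None:
    """Write records under the exact CSV column contract (empty cell =
    missing)."""
    # 17 significant digits: floats survive the CSV round trip exactly
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
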