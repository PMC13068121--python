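"""Per-subject raw vestibular measurements and their tabular form.

A :class:`RawRecord` holds one subject's raw laboratory measurements:
the six semicircular-canal vHIT gains (left/right lateral, anterior,
posterior), left/right cVEMP and oVEMP peak-to-peak amplitudes, the four
caloric slow-phase-velocity conditions, six signed SVV trial shifts, and
(for patients) the MRI-given affected side (-1 left, +1 right).

Missing measurements are represented as ``None``/NaN; VEMP, caloric and
SVV values go missing as whole test blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

GAIN_FIELDS = ("ll", "rl", "la", "ra", "lp", "rp")
CVEMP_FIELDS = ("cvemp_left", "cvemp_right")
OVEMP_FIELDS = ("ovemp_left", "ovemp_right")
CALORIC_FIELDS = (
    "caloric_right_cold",
    "caloric_right_warm",
    "caloric_left_cold",
    "caloric_left_warm",
)
SVV_COLUMNS = tuple(f"svv_{i}" for i in range(1, 7))

#: Exact CSV column contract, in order.
COLUMNS = (
    ("subject_id",)
    + GAIN_FIELDS
    + CVEMP_FIELDS
    + OVEMP_FIELDS
    + CALORIC_FIELDS
    + SVV_COLUMNS
    + ("true_side",)
)


def isna(x) -> bool:
    """True for None or NaN."""
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class CanalGains:
    """The six vHIT VOR gains of one subject (dimensionless)."""

    ll: Optional[float] = None
    rl: Optional[float] = None
    la: Optional[float] = None
    ra: Optional[float] = None
    lp: Optional[float] = None
    rp: Optional[float] = None


@dataclass(frozen=True)
class RawRecord:
    """All raw test measurements of one subject plus the optional side label."""

    subject_id: str
    ll: Optional[float] = None
    rl: Optional[float] = None
    la: Optional[float] = None
    ra: Optional[float] = None
    lp: Optional[float] = None
    rp: Optional[float] = None
    cvemp_left: Optional[float] = None
    cvemp_right: Optional[float] = None
    ovemp_left: Optional[float] = None
    ovemp_right: Optional[float] = None
    caloric_right_cold: Optional[float] = None
    caloric_right_warm: Optional[float] = None
    caloric_left_cold: Optional[float] = None
    caloric_left_warm: Optional[float] = None
    svv_trials: tuple = (None,) * 6
    true_side: Optional[int] = None

    def __post_init__(self):
        if len(self.svv_trials) != 6:
            raise ValueError("svv_trials must have exactly six slots")

    def gains(self) -> CanalGains:
        return CanalGains(**{f: getattr(self, f) for f in GAIN_FIELDS})

    def with_gains(self, gains: CanalGains) -> "RawRecord":
        return replace(self, **{f: getattr(gains, f) for f in GAIN_FIELDS})


def mirror_record(rec: RawRecord) -> RawRecord:
    """Swap every left/right raw measurement (and negate the signed SVV
    shifts, whose sign encodes side); the true side label flips too.

    Used to express the mirror-antisymmetry invariant of the asymmetry
    metrics: a fully mirrored subject must yield exactly negated canonical
    asymmetries.
    """
    svv = tuple(None if isna(t) else -t for t in rec.svv_trials)
    return replace(
        rec,
        ll=rec.rl,
        rl=rec.ll,
        la=rec.ra,
        ra=rec.la,
        lp=rec.rp,
        rp=rec.lp,
        cvemp_left=rec.cvemp_right,
        cvemp_right=rec.cvemp_left,
        ovemp_left=rec.ovemp_right,
        ovemp_right=rec.ovemp_left,
        caloric_right_cold=rec.caloric_left_cold,
        caloric_right_warm=rec.caloric_left_warm,
        caloric_left_cold=rec.caloric_right_cold,
        caloric_left_warm=rec.caloric_right_warm,
        svv_trials=svv,
        true_side=None if rec.true_side is None else -rec.true_side,
    )


def records_to_frame(records: Iterable[RawRecord]) -> pd.DataFrame:
    """Tabulate records with the exact CSV column contract."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id}
        for f in GAIN_FIELDS + CVEMP_FIELDS + OVEMP_FIELDS + CALORIC_FIELDS:
            v = getattr(r, f)
            row[f] = np.nan if isna(v) else v
        for i, c in enumerate(SVV_COLUMNS):
            v = r.svv_trials[i]
            row[c] = np.nan if isna(v) else v
        row["true_side"] = np.nan if r.true_side is None else r.true_side
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[RawRecord]:
    """Inverse of :func:`records_to_frame`."""

    def val(x):
        return None if pd.isna(x) else float(x)

    out = []
    for _, row in df.iterrows():
        kwargs = {
            f: val(row[f])
            for f in GAIN_FIELDS + CVEMP_FIELDS + OVEMP_FIELDS + CALORIC_FIELDS
        }
        side = row["true_side"]
        out.append(
            RawRecord(
                subject_id=str(row["subject_id"]),
                svv_trials=tuple(val(row[c]) for c in SVV_COLUMNS),
                true_side=None if pd.isna(side) else int(side),
                **kwargs,
            )
        )
    return out
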