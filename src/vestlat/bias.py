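"""Monocular-vHIT gain-bias estimation and removal.

Right-eye monocular vHIT recording systematically inflates the measured
eye's side: right-canal gains read higher than left-canal gains even in
vestibularly normal subjects.  The normative left-minus-right mean gain
difference of a comparison group estimates that offset; subtracting it
from patient gains removes the bias so that the remaining asymmetry
reflects pathology.

The offset is defined on the left-minus-right scale, so by default it is
subtracted from the *left* gain of each pair, which makes
``corrected difference = raw difference - offset`` hold exactly.  The
alternative ``side='split'`` removes half from each side (this variant
commutes with a full left/right mirror of the raw data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError
from .records import CanalGains, RawRecord, isna

__all__ = [
    "OffsetEstimate",
    "estimate_offset",
    "apply_offset",
    "correct_records",
    "left_right_ttests",
]

logger = logging.getLogger("vestlat")

#: Canal pairs as (name, left field, right field).
_PAIRS = (("lateral", "ll", "rl"), ("anterior", "la", "ra"), ("posterior", "lp", "rp"))

#: Corrected gains are floored here to keep ratio denominators positive.
GAIN_FLOOR = 0.01


@dataclass(frozen=True)
class OffsetEstimate:
    """Mean left-minus-right gain difference per canal pair, with the
    per-pair sample size and standard error."""

    lateral: float
    anterior: float
    posterior: float
    n: dict
    se: dict

    def get(self, pair: str) -> float:
        return getattr(self, pair)

    @classmethod
    def zero(cls) -> "OffsetEstimate":
        return cls(0.0, 0.0, 0.0, n={}, se={})


def _pair_diffs(subjects: Iterable[CanalGains]) -> dict:
    subjects = list(subjects)
    out = {}
    for name, lf, rf in _PAIRS:
        diffs = [
            getattr(g, lf) - getattr(g, rf)
            for g in subjects
            if not (isna(getattr(g, lf)) or isna(getattr(g, rf)))
        ]
        out[name] = np.asarray(diffs, dtype=float)
    return out


def _as_gains(subjects: Sequence) -> list[CanalGains]:
    return [s.gains() if isinstance(s, RawRecord) else s for s in subjects]


def estimate_offset(controls: Sequence) -> OffsetEstimate:
    """Estimate the normative gain bias from a comparison group.

    Accepts ``CanalGains`` or ``RawRecord`` objects; a subject missing a
    member of a pair is excluded from that pair's mean.
    """
    diffs = _pair_diffs(_as_gains(controls))
    means, ns, ses = {}, {}, {}
    for name, d in diffs.items():
        if len(d) < 2:
            raise EstimationError(
                f"need >= 2 complete {name} gain pairs to estimate the offset, got {len(d)}"
            )
        means[name] = float(np.mean(d))
        ns[name] = int(len(d))
        ses[name] = float(np.std(d, ddof=1) / math.sqrt(len(d)))
    return OffsetEstimate(
        lateral=means["lateral"],
        anterior=means["anterior"],
        posterior=means["posterior"],
        n=ns,
        se=ses,
    )


def apply_offset(
    gains: CanalGains, offset: OffsetEstimate, side: str = "left", floor: float = GAIN_FLOOR
) -> CanalGains:
    """Remove the estimated bias from one subject's gains.

    ``side='left'`` subtracts the whole left-minus-right offset from the
    left gain of each pair; ``side='split'`` shares it half-and-half.
    Corrected gains are floored at ``floor`` (occurrences are logged).
    """
    if side not in {"left", "split"}:
        raise ValueError("side must be 'left' or 'split'")
    vals = {f: getattr(gains, f) for f in ("ll", "rl", "la", "ra", "lp", "rp")}
    floored = 0
    for name, lf, rf in _PAIRS:
        off = offset.get(name)
        l_shift = off if side == "left" else off / 2.0
        r_shift = 0.0 if side == "left" else -off / 2.0
        for f, shift in ((lf, l_shift), (rf, r_shift)):
            if not isna(vals[f]):
                corrected = vals[f] - shift
                if corrected < floor:
                    corrected = floor
                    floored += 1
                vals[f] = corrected
    if floored:
        logger.warning("apply_offset: floored %d corrected gain(s) at %g", floored, floor)
    return CanalGains(**vals)


def correct_records(
    records: Sequence[RawRecord], offset: OffsetEstimate, side: str = "left"
) -> list[CanalGains]:
    """Bias-corrected gains for a sequence of records (one entry each)."""
    return [apply_offset(r.gains(), offset, side=side) for r in records]


def left_right_ttests(subjects: Sequence) -> pd.DataFrame:
    """One-sample t-tests of the per-pair left-minus-right gain
    differences against zero (two-sided).

    Returns a frame indexed by canal pair with columns
    ``mean_diff, t, df, p, n``.  Degenerate zero-variance samples report
    the limiting p (0 for a nonzero mean, 1 otherwise).
    """
    diffs = _pair_diffs(_as_gains(subjects))
    rows = {}
    for name, d in diffs.items():
        if len(d) < 2:
            raise EstimationError(f"need >= 2 complete {name} gain pairs for a t-test")
        mean = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        df = len(d) - 1
        if sd == 0.0:
            if mean == 0.0:
                t, p = 0.0, 1.0
            else:
                t, p = math.copysign(math.inf, mean), 0.0
                logger.warning("left_right_ttests: zero variance with nonzero mean (%s)", name)
        else:
            res = stats.ttest_1samp(d, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        rows[name] = {"mean_diff": mean, "t": t, "df": df, "p": p, "n": len(d)}
    return pd.DataFrame.from_dict(rows, orient="index")
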