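"""Left-right asymmetry statistics of the vestibular test battery.

All ratio metrics are Jongkees-style normalized differences scaled to
percent, hence bounded in [-100, 100]:

* ``rlll``   — lateral-canal gain asymmetry, (LL - RL)/(RL + LL) * 100
* ``ralp``   — right-anterior/left-posterior plane, (LP - RA)/(RA + LP) * 100
* ``larp``   — left-anterior/right-posterior plane, (LA - RP)/(LA + RP) * 100
* ``cmp_a``, ``cmp_b`` — composite vertical-canal measures built from the
  RALP/LARP fractions (``cmp_b`` is their plain average; algebraically it
  expands to (LA*LP - RA*RP) over the sum of all four pairwise gain
  products)
* ``cmp_ap`` — the composite anterior-posterior statistic: the Jongkees
  ratio of the gain *products* RP*LP and RA*LA
* ``vemp_ar`` — VEMP amplitude asymmetry ratio, (R - L)/(R + L) * 100
* ``caloric_cp`` — canal paresis over the four irrigation conditions
* ``svv_shift`` — mean signed verticality shift over six trials, degrees

Sign conventions differ between the as-printed formulas (the vHIT ratios
are left-minus-right; VEMP and caloric are right-minus-left), so a
canonicalization step re-signs every metric to a single orientation:
**positive = right side affected** (better left-side function).

Missing inputs propagate as missing metrics; imputation happens in the
preprocessing layer, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ORIENTATION, THRESHOLDS
from .exceptions import DomainError, StateError
from .records import CanalGains, RawRecord, isna

__all__ = [
    "METRICS",
    "AsymmetryProfile",
    "PathFlags",
    "rlll",
    "ralp",
    "larp",
    "cmp_a",
    "cmp_b",
    "cmp_ap",
    "vemp_ar",
    "caloric_cp",
    "svv_shift",
    "profile_from_record",
    "canonicalize_signs",
    "pathological_flags",
    "asymmetry_table",
]

#: Fixed column order of the per-patient metric table.
METRICS = (
    "rlll",
    "ralp",
    "larp",
    "cmp_ap",
    "ovemp_ar",
    "cvemp_ar",
    "caloric_cp",
    "svv_shift",
)


def _ratio(num: float, den: float, what: str) -> float:
    if den <= 0:
        raise DomainError(f"{what}: nonpositive denominator ({den!r})")
    return num / den * 100.0


def rlll(ll: float, rl: float) -> float:
    """Lateral-canal gain asymmetry percent (left minus right)."""
    return _ratio(ll - rl, rl + ll, "rlll")


def ralp(lp: float, ra: float) -> float:
    """RALP-plane asymmetry percent: left posterior vs right anterior."""
    return _ratio(lp - ra, ra + lp, "ralp")


def larp(la: float, rp: float) -> float:
    """LARP-plane asymmetry percent: left anterior vs right posterior."""
    return _ratio(la - rp, la + rp, "larp")


def cmp_a(la: float, ra: float, lp: float, rp: float) -> float:
    """Composite vertical-canal ratio of the gain products LA*LP and RA*RP."""
    return _ratio(la * lp - ra * rp, la * lp + ra * rp, "cmp_a")


def cmp_b(la: float, ra: float, lp: float, rp: float) -> float:
    """Mean of the RALP and LARP fractions, in percent.

    Algebraic identity (used as a self-check in the test suite):
    ``cmp_b = (LA*LP - RA*RP) / (LA*LP + RP*LP + RA*LA + RA*RP) * 100``.
    """
    if lp + ra <= 0 or la + rp <= 0:
        raise DomainError("cmp_b: nonpositive pairwise denominator")
    return ((lp - ra) / (lp + ra) + (la - rp) / (la + rp)) / 2.0 * 100.0


def cmp_b_expanded(la: float, ra: float, lp: float, rp: float) -> float:
    """The product-expansion form of :func:`cmp_b` (identical for all
    positive gains)."""
    den = la * lp + rp * lp + ra * la + ra * rp
    return _ratio(la * lp - ra * rp, den, "cmp_b_expanded")


def cmp_ap(la: float, ra: float, lp: float, rp: float) -> float:
    """Composite anterior-posterior asymmetry: Jongkees ratio of the gain
    products RP*LP (posterior pair) and RA*LA (anterior pair), percent."""
    return _ratio(rp * lp - ra * la, rp * lp + ra * la, "cmp_ap")


def vemp_ar(right_amp: float, left_amp: float) -> float:
    """VEMP asymmetry ratio percent from peak-to-peak amplitudes
    (right minus left).  Both amplitudes zero = unmeasurable."""
    return _ratio(right_amp - left_amp, right_amp + left_amp, "vemp_ar")


def caloric_cp(
    right_cold: float, right_warm: float, left_cold: float, left_warm: float
) -> float:
    """Canal paresis percent over the four caloric conditions (Jongkees).
    A zero total response (bilateral areflexia) has no defined side."""
    num = (right_cold + right_warm) - (left_cold + left_warm)
    den = right_cold + right_warm + left_cold + left_warm
    return _ratio(num, den, "caloric_cp")


def svv_shift(trials: Sequence[Optional[float]]) -> float:
    """Mean signed verticality shift (degrees) over the available trials;
    NaN if every trial is missing."""
    vals = [t for t in trials if not isna(t)]
    if not vals:
        return math.nan
    return float(np.mean(vals))


@dataclass(frozen=True)
class AsymmetryProfile:
    """The eight per-patient asymmetry metrics with an explicit sign
    orientation ('as_printed' or 'canonical')."""

    rlll: float = math.nan
    ralp: float = math.nan
    larp: float = math.nan
    cmp_ap: float = math.nan
    ovemp_ar: float = math.nan
    cvemp_ar: float = math.nan
    caloric_cp: float = math.nan
    svv_shift: float = math.nan
    orientation: str = "as_printed"

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS}


def _maybe(fn, *args):
    """Evaluate a metric, mapping missing inputs to NaN and degenerate
    (zero-response) denominators to NaN as well — at the table level a
    side that cannot be defined is a missing value."""
    if any(isna(a) for a in args):
        return math.nan
    try:
        return fn(*args)
    except DomainError:
        return math.nan


def profile_from_record(
    rec: RawRecord, gains: Optional[CanalGains] = None
) -> AsymmetryProfile:
    """Compute the as-printed asymmetry profile of one subject.

    ``gains`` overrides the record's raw vHIT gains (used after the
    monocular-bias correction).
    """
    g = gains if gains is not None else rec.gains()
    return AsymmetryProfile(
        rlll=_maybe(rlll, g.ll, g.rl),
        ralp=_maybe(ralp, g.lp, g.ra),
        larp=_maybe(larp, g.la, g.rp),
        cmp_ap=_maybe(cmp_ap, g.la, g.ra, g.lp, g.rp),
        ovemp_ar=_maybe(vemp_ar, rec.ovemp_right, rec.ovemp_left),
        cvemp_ar=_maybe(vemp_ar, rec.cvemp_right, rec.cvemp_left),
        caloric_cp=_maybe(
            caloric_cp,
            rec.caloric_right_cold,
            rec.caloric_right_warm,
            rec.caloric_left_cold,
            rec.caloric_left_warm,
        ),
        svv_shift=svv_shift(rec.svv_trials),
        orientation="as_printed",
    )


def canonicalize_signs(profile: AsymmetryProfile) -> AsymmetryProfile:
    """Re-sign every metric so that positive means the right side is
    affected.  Applying this twice is a state error, not an involution."""
    if profile.orientation == "canonical":
        raise StateError("profile is already canonical")
    values = {m: ORIENTATION[m] * getattr(profile, m) for m in METRICS}
    return AsymmetryProfile(orientation="canonical", **values)


@dataclass(frozen=True)
class PathFlags:
    """Pathological-threshold indicators (None where the input is missing).

    Thresholds are strict: a lateral gain below 0.8, a vertical gain below
    0.7, |CP| above 25 %, |SVV shift| above 2.2 degrees.
    """

    lateral: Optional[bool] = None
    left_anterior: Optional[bool] = None
    right_anterior: Optional[bool] = None
    left_posterior: Optional[bool] = None
    right_posterior: Optional[bool] = None
    caloric: Optional[bool] = None
    svv: Optional[bool] = None


def pathological_flags(gains: CanalGains, profile: AsymmetryProfile) -> PathFlags:
    def lt(x, thr):
        return None if isna(x) else bool(x < thr)

    def gt_abs(x, thr):
        return None if isna(x) else bool(abs(x) > thr)

    lat = None
    if not (isna(gains.ll) or isna(gains.rl)):
        lat = bool(min(gains.ll, gains.rl) < THRESHOLDS["lateral_gain"])
    v = THRESHOLDS["vertical_gain"]
    return PathFlags(
        lateral=lat,
        left_anterior=lt(gains.la, v),
        right_anterior=lt(gains.ra, v),
        left_posterior=lt(gains.lp, v),
        right_posterior=lt(gains.rp, v),
        caloric=gt_abs(profile.caloric_cp, THRESHOLDS["caloric_cp"]),
        svv=gt_abs(profile.svv_shift, THRESHOLDS["svv_shift"]),
    )


def asymmetry_table(
    records: Sequence[RawRecord],
    gains: Optional[Sequence[CanalGains]] = None,
    canonical: bool = True,
) -> pd.DataFrame:
    """Per-patient metric table (rows = subjects, columns = METRICS).

    ``gains`` optionally substitutes bias-corrected vHIT gains, one entry
    per record.  With ``canonical=True`` (the default for any downstream
    scoring or classification) metrics are re-signed so positive = right
    side affected.
    """
    rows = []
    for i, rec in enumerate(records):
        prof = profile_from_record(rec, gains[i] if gains is not None else None)
        if canonical:
            prof = canonicalize_signs(prof)
        rows.append(prof.as_dict())
    idx = [rec.subject_id for rec in records]
    return pd.DataFrame(rows, index=idx, columns=list(METRICS)).astype(float)
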