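"""Synthetic cohort generator.

Simulates the statistical structure of a unilateral-vestibular-schwannoma
patient group and of a vestibularly normal comparison group at the level
of derived measurements (VOR gains, VEMP peak-to-peak amplitudes, caloric
slow-phase velocities, SVV trial shifts):

* lateralized deficits on the tumor side (reduced ipsilateral canal gains,
  VEMP amplitudes and caloric responses; verticality tilt toward the
  affected side);
* a systematic right-favoring monocular-vHIT gain bias applied to every
  subject, patients and controls alike;
* per-test-block missingness, occasional outliers, and a configurable
  per-test probability that a patient's asymmetry opposes the true side
  (pre-existing contralateral deficits, atypical responses, human error).

Each subject draws from an independent RNG stream derived from
``(seed, group, subject index)``, so enlarging a cohort never changes
previously generated subjects, and a fixed seed reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .config import MissingRates, SyntheticConfig, validated
from .records import RawRecord

__all__ = ["generate_cohort", "generate_controls", "inject_missingness"]

_PATIENT_TAG = 0
_CONTROL_TAG = 1
_MISSING_TAG = 2

#: Test blocks that can flip direction independently. Flipping a block
#: regenerates it as if the tumor were on the opposite side while the
#: true label is unchanged, emulating asymmetries unexplained by the
#: tumor (which are test-specific phenomena: a pre-existing contralateral
#: deficit, an atypically enhanced response, a mis-run test).
_FLIP_BLOCKS = ("vhit", "cvemp", "ovemp", "caloric", "svv")


def _rng(seed: int, tag: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, tag, index])


def _trunc_normal(rng, mean, sd, lo=0.05):
    return max(float(rng.normal(mean, sd)), lo)


def _simulate_subject(cfg: SyntheticConfig, index: int, is_control: bool) -> RawRecord:
    tag = _CONTROL_TAG if is_control else _PATIENT_TAG
    rng = _rng(cfg.seed, tag, index)

    if is_control:
        side = None
        eff = {b: 0 for b in _FLIP_BLOCKS}  # 0 = no deficit
    else:
        side = 1 if rng.random() < cfg.p_right else -1
        flips = {b: rng.random() < cfg.p_flip for b in _FLIP_BLOCKS}
        eff = {b: (-side if flips[b] else side) for b in _FLIP_BLOCKS}

    d, base, noise = cfg.deficit, cfg.baseline, cfg.noise

    # --- vHIT gains -----------------------------------------------------
    def gain(canal_side: int, kind) -> float:
        # canal_side: -1 left canal, +1 right canal
        if eff["vhit"] == canal_side and eff["vhit"] != 0:
            return _trunc_normal(rng, kind.affected_mean, kind.affected_sd)
        return _trunc_normal(rng, kind.unaffected_mean, kind.unaffected_sd)

    ll = gain(-1, d.lateral)
    rl = gain(+1, d.lateral)
    la = gain(-1, d.vertical)
    ra = gain(+1, d.vertical)
    lp = gain(-1, d.vertical)
    rp = gain(+1, d.vertical)
    # Recording bias is stated as left-minus-right, so the right gain of
    # each pair is inflated by its negative.
    rl = max(rl - cfg.vhit_bias.lateral, 0.05)
    ra = max(ra - cfg.vhit_bias.anterior, 0.05)
    rp = max(rp - cfg.vhit_bias.posterior, 0.05)

    # --- VEMPs ----------------------------------------------------------
    def vemp_pair(block: str, mean, sd, factor):
        b = _trunc_normal(rng, mean, sd, lo=1.0)  # shared subject baseline
        fl = factor if eff[block] == -1 else 1.0
        fr = factor if eff[block] == +1 else 1.0
        left = b * fl * float(np.exp(rng.normal(0.0, noise.vemp_sigma)))
        right = b * fr * float(np.exp(rng.normal(0.0, noise.vemp_sigma)))
        return left, right

    cvemp_left, cvemp_right = vemp_pair("cvemp", base.cvemp_mean, base.cvemp_sd, d.cvemp_factor)
    ovemp_left, ovemp_right = vemp_pair("ovemp", base.ovemp_mean, base.ovemp_sd, d.ovemp_factor)

    # --- Caloric --------------------------------------------------------
    spv_base = float(rng.gamma(base.caloric_shape, base.caloric_scale))
    fl = d.caloric_factor if eff["caloric"] == -1 else 1.0
    fr = d.caloric_factor if eff["caloric"] == +1 else 1.0

    def spv(f):
        return spv_base * f * float(np.exp(rng.normal(0.0, noise.caloric_sigma)))

    caloric_right_cold = spv(fr)
    caloric_right_warm = spv(fr)
    caloric_left_cold = spv(fl)
    caloric_left_warm = spv(fl)

    # --- SVV ------------------------------------------------------------
    tilt = d.svv_tilt * eff["svv"]
    subject_bias = float(rng.normal(0.0, noise.svv_subject_sd))
    svv = tuple(
        tilt + subject_bias + float(rng.normal(0.0, noise.svv_trial_sd)) for _ in range(6)
    )

    rec = RawRecord(
        subject_id=("C" if is_control else "P") + f"{index:04d}",
        ll=ll,
        rl=rl,
        la=la,
        ra=ra,
        lp=lp,
        rp=rp,
        cvemp_left=cvemp_left,
        cvemp_right=cvemp_right,
        ovemp_left=ovemp_left,
        ovemp_right=ovemp_right,
        caloric_right_cold=caloric_right_cold,
        caloric_right_warm=caloric_right_warm,
        caloric_left_cold=caloric_left_cold,
        caloric_left_warm=caloric_left_warm,
        svv_trials=svv,
        true_side=side,
    )
    return _apply_outliers(rec, rng, cfg.outlier_rate)


def _apply_outliers(rec: RawRecord, rng, rate: float) -> RawRecord:
    """With probability ``rate`` per measurement, scale a gain/amplitude/SPV
    by 3 or shift an SVV trial by +15 degrees (to exercise winsorization)."""
    if rate <= 0:
        return rec
    from dataclasses import replace

    scale_fields = (
        "ll",
        "rl",
        "la",
        "ra",
        "lp",
        "rp",
        "cvemp_left",
        "cvemp_right",
        "ovemp_left",
        "ovemp_right",
        "caloric_right_cold",
        "caloric_right_warm",
        "caloric_left_cold",
        "caloric_left_warm",
    )
    changes = {}
    for f in scale_fields:
        if rng.random() < rate:
            changes[f] = getattr(rec, f) * 3.0
    svv = list(rec.svv_trials)
    touched = False
    for i in range(6):
        if rng.random() < rate:
            svv[i] = svv[i] + 15.0
            touched = True
    if touched:
        changes["svv_trials"] = tuple(svv)
    return replace(rec, **changes) if changes else rec


def generate_cohort(config: SyntheticConfig) -> list[RawRecord]:
    """Generate ``n_patients`` labelled patient records (then apply the
    configured per-test missingness)."""
    config = validated(SyntheticConfig, **config.model_dump())
    recs = [_simulate_subject(config, i, is_control=False) for i in range(config.n_patients)]
    return inject_missingness(recs, config.missing_rates, config.seed)


def generate_controls(config: SyntheticConfig) -> list[RawRecord]:
    """Generate ``n_controls`` unlabelled comparison records: no deficit,
    same recording bias and noise as patients."""
    config = validated(SyntheticConfig, **config.model_dump())
    recs = [_simulate_subject(config, i, is_control=True) for i in range(config.n_controls)]
    # Offset the missingness stream so patient and control blanking
    # patterns are independent for the same top-level seed.
    return inject_missingness(recs, config.missing_rates, (config.seed + 1_000_003) & 0x7FFFFFFF)


def inject_missingness(
    records: Sequence[RawRecord], missing_rates: MissingRates, seed: int
) -> list[RawRecord]:
    """Independently blank whole test blocks with their configured rates.

    Missingness is per block: all four caloric conditions vanish together,
    likewise both amplitudes of a VEMP, all six SVV trials, and all six
    vHIT gains (whose default rate is zero).
    """
    rates = validated(MissingRates, **missing_rates.model_dump())
    from dataclasses import replace

    out = []
    for i, rec in enumerate(records):
        rng = _rng(seed, _MISSING_TAG, i)
        changes = {}
        if rng.random() < rates.vhit:
            changes.update({f: None for f in ("ll", "rl", "la", "ra", "lp", "rp")})
        if rng.random() < rates.cvemp:
            changes.update(cvemp_left=None, cvemp_right=None)
        if rng.random() < rates.ovemp:
            changes.update(ovemp_left=None, ovemp_right=None)
        if rng.random() < rates.svv:
            changes["svv_trials"] = (None,) * 6
        if rng.random() < rates.caloric:
            changes.update(
                caloric_right_cold=None,
                caloric_right_warm=None,
                caloric_left_cold=None,
                caloric_left_warm=None,
            )
        out.append(replace(rec, **changes) if changes else rec)
    return out
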