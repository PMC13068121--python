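"""Unit and property tests of the asymmetry-metric layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vestlat import (
    AsymmetryProfile,
    CanalGains,
    DomainError,
    RawRecord,
    StateError,
    caloric_cp,
    canonicalize_signs,
    cmp_ap,
    cmp_b,
    larp,
    mirror_record,
    pathological_flags,
    profile_from_record,
    ralp,
    rlll,
    svv_shift,
    vemp_ar,
)
from vestlat.asymmetry import METRICS, cmp_b_expanded

gains = st.floats(min_value=0.1, max_value=1.5, allow_nan=False)


@pytest.mark.parametrize(
    "fn,args,expected",
    [
        (rlll, (1.0, 1.0), 0.0),
        (rlll, (0.8, 1.0), -100.0 / 9.0),
        (rlll, (1.0, 0.5), 100.0 / 3.0),
        (ralp, (0.7, 0.7), 0.0),
        (ralp, (0.9, 0.6), 20.0),
        (larp, (0.6, 0.9), -20.0),
        (cmp_ap, (0.6, 0.6, 0.8, 0.8), 28.0),  # (0.64-0.36)/(0.64+0.36)
        (cmp_ap, (0.8, 0.8, 0.6, 0.6), -28.0),
        (vemp_ar, (100.0, 100.0), 0.0),
        (vemp_ar, (100.0, 50.0), 100.0 / 3.0),
        (vemp_ar, (0.0, 50.0), -100.0),
        (caloric_cp, (10.0, 10.0, 10.0, 10.0), 0.0),
        (caloric_cp, (20.0, 25.0, 10.0, 15.0), 200.0 / 7.0),
        (caloric_cp, (0.0, 0.0, 10.0, 10.0), -100.0),
    ],
)
def test_ratio_metrics_against_direct_arithmetic(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=1e-9)


def test_nonpositive_denominators_are_domain_errors():
    with pytest.raises(DomainError):
        rlll(0.0, 0.0)
    with pytest.raises(DomainError):
        vemp_ar(0.0, 0.0)
    with pytest.raises(DomainError):
        caloric_cp(0.0, 0.0, 0.0, 0.0)


def test_svv_shift_averages_available_trials():
    assert svv_shift((0, 0, 0, 0, 0, 0)) == 0.0
    assert svv_shift((-3, -2, -4, -3, -2, -4)) == pytest.approx(-3.0)
    assert svv_shift((2.0, None, 4.0, None, None, None)) == pytest.approx(3.0)
    assert math.isnan(svv_shift((None,) * 6))


@given(la=gains, ra=gains, lp=gains, rp=gains)
@settings(max_examples=300, derandomize=True)
def test_cmp_b_equals_its_product_expansion(la, ra, lp, rp):
    assert cmp_b(la, ra, lp, rp) == pytest.approx(
        cmp_b_expanded(la, ra, lp, rp), abs=1e-10
    )


@given(a=gains, b=gains, c=st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=200, derandomize=True)
def test_ratio_scale_invariance_and_bounds(a, b, c):
    assert rlll(c * a, c * b) == pytest.approx(rlll(a, b), rel=1e-9, abs=1e-9)
    assert -100.0 <= rlll(a, b) <= 100.0
    assert vemp_ar(c * a, c * b) == pytest.approx(vemp_ar(a, b), rel=1e-9, abs=1e-9)


def _record(**kw):
    base = dict(
        subject_id="p",
        ll=0.9,
        rl=0.7,
        la=0.85,
        ra=0.6,
        lp=0.8,
        rp=0.65,
        cvemp_left=120.0,
        cvemp_right=60.0,
        ovemp_left=10.0,
        ovemp_right=6.0,
        caloric_right_cold=8.0,
        caloric_right_warm=10.0,
        caloric_left_cold=20.0,
        caloric_left_warm=25.0,
        svv_trials=(1.0, 2.0, 1.5, 0.5, 1.0, 1.2),
        true_side=1,
    )
    base.update(kw)
    return RawRecord(**base)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, derandomize=True)
def test_mirror_antisymmetry_of_canonical_profile(seed):
    """A full left/right swap of the raw measurements negates every
    canonical metric exactly."""
    rng = np.random.default_rng(seed)
    rec = _record(
        ll=rng.uniform(0.3, 1.2),
        rl=rng.uniform(0.3, 1.2),
        la=rng.uniform(0.3, 1.2),
        ra=rng.uniform(0.3, 1.2),
        lp=rng.uniform(0.3, 1.2),
        rp=rng.uniform(0.3, 1.2),
        cvemp_left=rng.uniform(10, 300),
        cvemp_right=rng.uniform(10, 300),
        ovemp_left=rng.uniform(1, 30),
        ovemp_right=rng.uniform(1, 30),
        caloric_right_cold=rng.uniform(1, 40),
        caloric_right_warm=rng.uniform(1, 40),
        caloric_left_cold=rng.uniform(1, 40),
        caloric_left_warm=rng.uniform(1, 40),
        svv_trials=tuple(rng.uniform(-10, 10, size=6)),
    )
    p = canonicalize_signs(profile_from_record(rec))
    q = canonicalize_signs(profile_from_record(mirror_record(rec)))
    # Mirroring maps the RALP plane onto the LARP plane (the right
    # anterior canal becomes the left anterior canal), so those two
    # metrics negate as a pair.  The composite anterior-posterior ratio
    # compares the side-symmetric products RP*LP and RA*LA and is
    # therefore mirror-invariant (it carries no left-right information).
    # All remaining metrics negate individually.
    for m in ("rlll", "ovemp_ar", "cvemp_ar", "caloric_cp", "svv_shift"):
        assert getattr(q, m) == pytest.approx(-getattr(p, m), rel=1e-12, abs=1e-12)
    assert q.ralp == pytest.approx(-p.larp, rel=1e-12, abs=1e-12)
    assert q.larp == pytest.approx(-p.ralp, rel=1e-12, abs=1e-12)
    assert q.cmp_ap == pytest.approx(p.cmp_ap, rel=1e-12, abs=1e-12)


def test_canonicalization_sign_map_and_state_guard():
    rec = _record()
    p = profile_from_record(rec)
    # as printed: caloric right responses weaker (canal paresis right)
    assert p.caloric_cp < 0
    c = canonicalize_signs(p)
    # canonical: positive = right side affected
    assert c.caloric_cp == pytest.approx(-p.caloric_cp)
    assert c.cvemp_ar == pytest.approx(-p.cvemp_ar)
    assert c.ovemp_ar == pytest.approx(-p.ovemp_ar)
    assert c.rlll == pytest.approx(p.rlll)  # already left-minus-right
    assert c.svv_shift == pytest.approx(p.svv_shift)
    with pytest.raises(StateError):
        canonicalize_signs(c)


def test_canonical_caloric_example():
    # as-printed CP = +30 means stronger right responses, i.e. the left
    # side is hypofunctional -> canonical value is -30 (left affected).
    p = AsymmetryProfile(caloric_cp=30.0)
    assert canonicalize_signs(p).caloric_cp == -30.0


def test_pathological_flags_thresholds_are_strict():
    g = CanalGains(ll=0.79, rl=1.0, la=0.7, ra=0.69, lp=0.8, rp=0.9)
    p = AsymmetryProfile(caloric_cp=25.0, svv_shift=-2.3)
    f = pathological_flags(g, p)
    assert f.lateral is True  # min gain 0.79 < 0.8
    assert f.left_anterior is False  # 0.7 is the boundary: normal
    assert f.right_anterior is True
    assert f.caloric is False  # CP = 25.0 is not > 25
    assert f.svv is True  # |-2.3| > 2.2

    p2 = AsymmetryProfile(svv_shift=2.2)
    assert pathological_flags(g, p2).svv is False  # boundary is normal
    assert pathological_flags(CanalGains(), p2).lateral is None


def test_missing_inputs_propagate_as_missing_metrics():
    rec = _record(caloric_right_cold=None, caloric_right_warm=None,
                  caloric_left_cold=None, caloric_left_warm=None)
    p = profile_from_record(rec)
    assert math.isnan(p.caloric_cp)
    assert not math.isnan(p.rlll)
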