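"""Tests of the fold-aware preprocessing model."""

import math

import numpy as np
import pandas as pd
import pytest

from vestlat import ImputationError, PreprocessModel
from vestlat.preprocess import impute_1nn, normalize_range, standardize, winsorize


def frame(rows, cols=None):
    return pd.DataFrame(rows, columns=cols or [f"m{i}" for i in range(len(rows[0]))], dtype=float)


# -- imputation ----------------------------------------------------------


def test_1nn_imputes_from_the_nearest_training_row():
    train = frame([[1, 2, 3], [10, 20, 30]])
    pm = PreprocessModel(steps=("impute",)).fit(train)
    q = frame([[1, 2, np.nan]])
    out = impute_1nn(q, pm)
    assert out.iloc[0].tolist() == [1, 2, 3]


def test_complete_rows_are_unchanged():
    train = frame([[1, 2, 3], [10, 20, 30]])
    pm = PreprocessModel(steps=("impute",)).fit(train)
    q = frame([[5.0, 6.0, 7.0]])
    assert impute_1nn(q, pm).iloc[0].tolist() == [5.0, 6.0, 7.0]


def test_equidistant_tie_goes_to_the_smaller_row_index():
    train = frame([[0, 0, 5], [2, 0, 7], [-2, 0, 9]])  # rows 1,2 equidistant from q
    pm = PreprocessModel(steps=("impute",)).fit(train)
    q = frame([[0, 1, np.nan]])
    # distances: row0 -> 1.0-ish smallest; force tie between rows 1 and 2
    q2 = frame([[0, 0, np.nan]])
    out = impute_1nn(q2, pm)
    assert out.iloc[0, 2] == 5  # row 0 exact match
    pm2 = PreprocessModel(steps=("impute",)).fit(frame([[2, 0, 7], [-2, 0, 9]]))
    out2 = impute_1nn(frame([[0, 0, np.nan]]), pm2)
    assert out2.iloc[0, 2] == 7  # tie -> first training row


def test_fit_imputation_leaves_self_out():
    # row 0 is missing m2; its nearest *other* row must donate
    train = frame([[1, 2, np.nan], [1, 2, 3], [9, 9, 9]])
    pm = PreprocessModel(steps=("impute",)).fit(train)
    assert pm.train_imputed_[0, 2] == 3


def test_rows_without_observed_values_are_imputation_errors():
    train = frame([[1.0, 2.0], [3.0, 4.0]])
    pm = PreprocessModel(steps=("impute",)).fit(train)
    with pytest.raises(ImputationError):
        impute_1nn(frame([[np.nan, np.nan]]), pm)
    with pytest.raises(ImputationError):
        # a training column observed nowhere cannot be imputed at fit time
        PreprocessModel(steps=("impute",)).fit(frame([[np.nan, 2.0], [np.nan, 3.0]]))


def test_distance_rescaling_prefers_fully_shared_rows():
    # query shares 2 columns with row 0 (small diffs) and 1 column with
    # row 1 (exact match); rescaling by n_cols/n_shared penalizes row 1.
    train = frame([[1.0, 1.0, 0.2], [np.nan, np.nan, 0.0]])
    pm = PreprocessModel(steps=("impute",)).fit(train)
    out = impute_1nn(frame([[1.1, 1.1, np.nan]]), pm)
    assert out.iloc[0, 2] == 0.2


# -- winsorization -------------------------------------------------------


def test_winsorization_uses_most_extreme_in_range_training_value():
    col = [0.0] * 10 + [100.0]
    train = frame([[v] for v in col], cols=["x"])
    pm = PreprocessModel(steps=("winsorize",)).fit(train)
    mean, sd = np.mean(col), np.std(col, ddof=1)
    assert pm.winsor_upper_[0] == pytest.approx(mean + 2 * sd)
    out = winsorize(frame([[100.0]], cols=["x"]), pm)
    assert out.iloc[0, 0] == 0.0  # largest training value inside the bound


def test_in_range_values_pass_winsorization_unchanged():
    train = frame([[-5.0], [0.0], [5.0]], cols=["x"])
    pm = PreprocessModel(steps=("winsorize",)).fit(train)
    out = winsorize(train, pm)
    pd.testing.assert_frame_equal(out, train)
    assert ((out["x"] >= pm.winsor_lower_[0]) & (out["x"] <= pm.winsor_upper_[0])).all()


def test_winsorized_outputs_lie_within_bounds():
    rng = np.random.default_rng(0)
    train = frame(rng.normal(size=(50, 3)))
    pm = PreprocessModel(steps=("winsorize",)).fit(train)
    test = frame(rng.normal(scale=5, size=(50, 3)))
    out = winsorize(test, pm).to_numpy()
    assert (out >= pm.winsor_lower_ - 1e-12).all()
    assert (out <= pm.winsor_upper_ + 1e-12).all()


# -- normalization / standardization --------------------------------------


def test_range_normalization_divides_by_training_range():
    train = frame([[-50.0], [0.0], [50.0]], cols=["x"])
    pm = PreprocessModel(steps=("normalize",)).fit(train)
    out = normalize_range(train, pm)
    assert out["x"].tolist() == [-0.5, 0.0, 0.5]


def test_constant_column_is_dropped_by_normalization():
    train = frame([[1.0, 1.0], [2.0, 1.0]], cols=["a", "b"])
    pm = PreprocessModel(steps=("normalize",)).fit(train)
    out = pm.transform(train)
    assert list(out.columns) == ["a"]


def test_standardize_matches_hand_arithmetic():
    train = frame([[1.0], [2.0], [3.0]], cols=["x"])
    pm = PreprocessModel(steps=("standardize",)).fit(train)
    out = standardize(train, pm)
    assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
    held = standardize(frame([[2.0]], cols=["x"]), pm)
    assert held.iloc[0, 0] == 0.0  # value at the training mean


def test_standardize_is_affine_invariant():
    rng = np.random.default_rng(1)
    x = frame(rng.normal(size=(20, 2)))
    ax = x * 3.0 + 7.0
    z1 = PreprocessModel(steps=("standardize",)).fit(x).transform(x)
    z2 = PreprocessModel(steps=("standardize",)).fit(ax).transform(ax)
    pd.testing.assert_frame_equal(z1, z2, atol=1e-12)


# -- model-level invariants ------------------------------------------------


def test_winsorization_is_idempotent_under_the_same_model():
    """A fitted winsorizer maps its own output to itself: everything is
    already inside the bounds after one pass."""
    rng = np.random.default_rng(2)
    train = frame(rng.normal(size=(30, 3)))
    pm = PreprocessModel(steps=("winsorize",)).fit(train)
    test = frame(rng.normal(scale=4, size=(20, 3)))
    once = pm.transform(test)
    pd.testing.assert_frame_equal(pm.transform(once), once, atol=1e-12)


@pytest.mark.parametrize("steps", [("normalize",), ("standardize",)])
def test_rescaling_refit_on_own_output_is_identity(steps):
    """Unit-range / unit-variance training output rescales to itself
    when the model is refitted on it."""
    rng = np.random.default_rng(2)
    train = frame(rng.normal(size=(30, 3)))
    once = PreprocessModel(steps=steps).fit(train).transform(train)
    twice = PreprocessModel(steps=steps).fit(once).transform(once)
    pd.testing.assert_frame_equal(once, twice, atol=1e-12)


def test_fitted_model_is_independent_of_held_out_rows():
    """No leakage: the fitted statistics never depend on rows outside
    the training fold."""
    rng = np.random.default_rng(3)
    train = frame(rng.normal(size=(25, 4)))
    pm = PreprocessModel().fit(train)
    q1 = frame(rng.normal(size=(1, 4)))
    q2 = q1 * 100.0
    np.testing.assert_array_equal(pm.std_mean_, PreprocessModel().fit(train).std_mean_)
    # transforming wildly different held-out rows leaves the model unchanged
    pm.transform(q1)
    mean_before = pm.std_mean_.copy()
    pm.transform(q2)
    np.testing.assert_array_equal(pm.std_mean_, mean_before)
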