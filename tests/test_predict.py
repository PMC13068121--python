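"""Tests of the LOOCV prediction, ROC/AUC and bootstrap layer."""

import numpy as np
import pandas as pd
import pytest

from vestlat import (
    ClassifierSpec,
    ConfigurationError,
    auc_ci,
    auc_mannwhitney,
    compare_classifiers,
    grouped_models,
    loocv_scores,
    optimal_operating_point,
    paired_bootstrap_auc_test,
    roc,
    stepwise_auc,
    svm_feature_ranking,
)
from conftest import separable_features


def fold_frame(scores, truth):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    return pd.DataFrame(
        {
            "score": scores,
            "pred": np.where(scores >= 0, 1, -1),
            "truth": truth,
            "fold": np.arange(len(scores)),
        }
    )


def exhaustive_auc(scores, truth):
    """Independent oracle: explicit pairwise concordance with ties 1/2."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize(
    "scores,truth,expected",
    [
        ([2, 3, 0, 1], [1, 1, -1, -1], 1.0),
        ([0.9, 0.4, 0.5, 0.1], [1, 1, -1, -1], 0.75),
        ([1, 1, 1, 1], [1, 1, -1, -1], 0.5),
    ],
)
def test_auc_matches_pairwise_concordance_examples(scores, truth, expected):
    fs = fold_frame(scores, truth)
    assert roc(fs).auc == pytest.approx(expected, abs=1e-12)
    assert auc_mannwhitney(np.array(scores), np.array(truth)) == pytest.approx(
        expected, abs=1e-12
    )


def test_auc_equals_exhaustive_oracle_on_random_score_sets():
    rng = np.random.default_rng(5)
    for _ in range(40):
        n = int(rng.integers(4, 40))
        truth = np.concatenate([[1, -1], rng.choice([-1, 1], size=n - 2)])
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        fs = fold_frame(scores, truth)
        assert roc(fs).auc == pytest.approx(exhaustive_auc(scores, truth), abs=1e-12)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        roc(fold_frame([1.0, 2.0], [1, 1]))


def test_optimal_operating_point_maximizes_youden_j():
    fs = fold_frame([3, 2, 1, 0], [1, 1, -1, -1])
    oop = roc(fs).oop
    assert oop.sensitivity == 1.0 and oop.specificity == 1.0 and oop.youden_j == 1.0
    # the J of a (sens=1, spec=0.88) point is 0.88
    assert 1.0 + 0.88 - 1.0 == pytest.approx(0.88)
    # overlapping scores: J computed on the sweep
    fs2 = fold_frame([3, 1, 2, 0], [1, 1, -1, -1])
    oop2 = roc(fs2).oop
    assert oop2.youden_j == pytest.approx(0.5)
    assert oop2.sensitivity == 1.0  # tie broken toward higher sensitivity


def test_loocv_separable_cohort_is_perfect_and_deterministic():
    X, y = separable_features(n=16, gap=8.0, seed=1)
    fs = loocv_scores(X, y, features=["info"])
    assert (fs["pred"] == fs["truth"]).all()
    assert roc(fs).auc == 1.0
    fs2 = loocv_scores(X, y, features=["info"])
    pd.testing.assert_frame_equal(fs, fs2)


def test_duplicated_patients_get_identical_heldout_scores():
    X, y = separable_features(n=12, gap=3.0, seed=2)
    X2 = pd.concat([X, X.iloc[[0]], X.iloc[[0]]], ignore_index=True)
    y2 = np.concatenate([y, [y[0], y[0]]])
    fs = loocv_scores(X2, y2)
    dup = fs.iloc[[12, 13]]["score"].to_numpy()
    assert dup[0] == pytest.approx(dup[1], rel=1e-9)


def test_permuted_labels_give_near_chance_auc():
    rng = np.random.default_rng(6)
    X = pd.DataFrame({"a": rng.normal(size=68), "b": rng.normal(size=68)})
    y = np.array([1] * 34 + [-1] * 34)
    rng.shuffle(y)
    fs = loocv_scores(X, y)
    assert 0.3 < roc(fs).auc < 0.7


def test_label_and_feature_flip_leaves_auc_unchanged():
    X, y = separable_features(n=20, gap=2.0, seed=3)
    a = roc(loocv_scores(X, y)).auc
    b = roc(loocv_scores(-X, -y)).auc
    assert a == pytest.approx(b, abs=1e-9)


def test_bootstrap_ci_is_seeded_and_stable():
    X, y = separable_features(n=30, gap=1.0, seed=4, n_noise=0)
    fs = loocv_scores(X, y)
    ci1 = auc_ci(fs, n_boot=400, seed=9)
    ci2 = auc_ci(fs, n_boot=400, seed=9)
    assert ci1 == ci2
    ci3 = auc_ci(fs, n_boot=800, seed=10)
    assert ci1[0] == pytest.approx(ci3[0], abs=0.03)
    assert ci1[1] == pytest.approx(ci3[1], abs=0.03)
    lo, hi = auc_ci(fs, n_boot=400, seed=9)
    assert lo <= roc(fs).auc <= hi


def test_degenerate_perfect_separation_has_high_ci_floor():
    X, y = separable_features(n=68, gap=10.0, seed=5, n_noise=0)
    fs = loocv_scores(X, y)
    lo, _ = auc_ci(fs, n_boot=500, seed=0)
    assert lo >= 0.9


def test_paired_bootstrap_identical_scores_give_p_one():
    X, y = separable_features(n=20, gap=1.0, seed=6)
    fs = loocv_scores(X, y)
    assert paired_bootstrap_auc_test(fs, fs, n_boot=200, seed=0) == 1.0


def test_paired_bootstrap_detects_a_large_auc_gap():
    rng = np.random.default_rng(7)
    y = np.array([1] * 34 + [-1] * 34)
    strong = fold_frame(y * 3.0 + rng.normal(0, 0.3, 68), y)
    null = fold_frame(rng.normal(size=68), y)
    p = paired_bootstrap_auc_test(strong, null, n_boot=500, seed=1)
    assert p < 0.01


def test_svm_ranking_puts_the_informative_metric_first():
    hits = 0
    for seed in range(10):
        X, y = separable_features(n=40, gap=2.0, seed=seed, n_noise=3)
        order, weights = svm_feature_ranking(X, y)
        hits += order[0] == "info"
        # sign flip leaves |weight| and rank unchanged
        Xf = X.copy()
        Xf["info"] = -Xf["info"]
        order_f, weights_f = svm_feature_ranking(Xf, y)
        assert order_f[0] == order[0]
        assert abs(weights_f["info"]) == pytest.approx(abs(weights["info"]), rel=1e-3)
    assert hits >= 9


def test_duplicated_informative_metric_occupies_top_ranks():
    X, y = separable_features(n=40, gap=2.0, seed=1, n_noise=2)
    X = X.copy()
    X["info_copy"] = X["info"] + np.random.default_rng(0).normal(0, 1e-6, len(X))
    order, _ = svm_feature_ranking(X, y)
    assert set(order[:2]) == {"info", "info_copy"}


def test_stepwise_trace_is_consistent_and_noise_tolerant():
    X, y = separable_features(n=40, gap=2.0, seed=8, n_noise=4)
    order, _ = svm_feature_ranking(X, y)
    trace = stepwise_auc(X, y, order, n_boot=100, seed=0)
    assert len(trace.aucs) == X.shape[1]
    # k=1 equals the univariate AUC of the top metric
    uni = roc(loocv_scores(X, y, features=[order[0]])).auc
    assert trace.aucs[0] == pytest.approx(uni)
    # appending pure-noise metrics never degrades the AUC materially
    assert max(trace.aucs) - trace.aucs[-1] < 0.05
    assert 1 <= trace.plateau_k <= X.shape[1]


def test_two_strong_metrics_combine_without_loss():
    rng = np.random.default_rng(9)
    y = np.array([1, -1] * 40)
    n = len(y)
    X = pd.DataFrame(
        {
            "caloric_like": y * 2.0 + rng.normal(0, 1.0, n),
            "cvemp_like": y * 1.5 + rng.normal(0, 1.0, n),
        }
    )
    auc_uni = max(
        roc(loocv_scores(X, y, features=[c])).auc for c in X.columns
    )
    auc_comb = roc(loocv_scores(X, y)).auc
    assert auc_comb >= auc_uni - 0.01


def test_grouped_models_contrast_and_empty_group_error():
    rng = np.random.default_rng(10)
    y = np.array([1, -1] * 17)
    n = len(y)
    X = pd.DataFrame(
        {
            "rlll": rng.normal(size=n),
            "ralp": rng.normal(size=n),
            "larp": rng.normal(size=n),
            "cvemp_ar": y * 2.0 + rng.normal(0, 0.8, n),
            "ovemp_ar": y * 2.0 + rng.normal(0, 0.8, n),
        }
    )
    out = grouped_models(X, y, n_boot=100, seed=0)
    assert out["otolith"].auc > out["canal"].auc  # otolith-only deficit
    with pytest.raises(ConfigurationError):
        grouped_models(X, y, groups={"empty": ()}, n_boot=50)


def test_classifier_comparison_runs_all_three_families():
    X, y = separable_features(n=20, gap=2.0, seed=11, n_noise=1)
    table = compare_classifiers(X, y, n_boot=50, seed=0)
    assert set(table.index) == {"logistic", "naive_bayes", "linear_svm"}
    assert (table["auc"] > 0.8).all()
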