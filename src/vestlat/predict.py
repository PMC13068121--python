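"""Leave-one-out cross-validated prediction of the affected side.

For each patient a preprocessing model (1-NN imputation, winsorization,
z-scoring) and a classifier are fitted on the other n-1 patients, and
the held-out patient receives a signed decision score: log-odds for
logistic regression, log posterior ratio for Gaussian naive Bayes, the
signed margin for a linear SVM.  Positive scores predict the right side
(+1).  Pooled held-out scores feed the ROC analysis: trapezoidal AUC
(equal to the Mann-Whitney pairwise-concordance probability with ties
counted 1/2), stratified percentile-bootstrap confidence intervals, the
Youden-J optimal operating point, an SVM-weight feature ranking with a
stepwise multivariate AUC trace, and paired bootstrap AUC comparisons.

All hyperparameters are fixed a priori; nothing is tuned on the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC

from .exceptions import ConfigurationError, ConvergenceError
from .preprocess import PreprocessModel

__all__ = [
    "ClassifierSpec",
    "FoldScores",
    "RocResult",
    "OperatingPoint",
    "StepwiseTrace",
    "loocv_scores",
    "loocv_scores_multi",
    "roc",
    "auc_ci",
    "optimal_operating_point",
    "svm_feature_ranking",
    "stepwise_auc",
    "paired_bootstrap_auc_test",
    "grouped_models",
    "compare_classifiers",
    "METRIC_GROUPS",
]

logger = logging.getLogger("vestlat")

#: Decision scores are capped at this magnitude (log-odds) so that exact
#: separation inside a LOOCV training fold cannot produce infinities.
SCORE_CAP = 30.0

#: Physiologically defined metric groups: the three semicircular-canal
#: vHIT asymmetries as one proxy, the two otolith (VEMP) asymmetries as
#: the other.
METRIC_GROUPS = {
    "canal": ("rlll", "ralp", "larp"),
    "otolith": ("cvemp_ar", "ovemp_ar"),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family with fixed, a-priori hyperparameters."""

    family: str = "logistic"  # logistic_unregularized MLE
    max_iter: int = 200
    tol: float = 1e-8
    svm_cost: float = 1.0
    nb_var_floor: float = 1e-9

    def __post_init__(self):
        if self.family not in {"logistic", "naive_bayes", "linear_svm"}:
            raise ConfigurationError(f"unknown classifier family '{self.family}'")

    def make(self):
        if self.family == "logistic":
            # C=inf: plain unregularized maximum likelihood
            return LogisticRegression(
                C=np.inf, solver="lbfgs", max_iter=self.max_iter, tol=self.tol
            )
        if self.family == "naive_bayes":
            return GaussianNB(var_smoothing=self.nb_var_floor)
        return LinearSVC(C=self.svm_cost, max_iter=10_000, tol=self.tol, random_state=0)

    def score_of(self, clf, X: np.ndarray) -> np.ndarray:
        if self.family == "naive_bayes":
            lp = clf.predict_log_proba(X)
            pos = int(np.flatnonzero(clf.classes_ == 1)[0])
            neg = int(np.flatnonzero(clf.classes_ == -1)[0])
            s = lp[:, pos] - lp[:, neg]
        else:
            s = clf.decision_function(X)
        return np.clip(s, -SCORE_CAP, SCORE_CAP)


#: Pooled held-out scores: one row per patient with columns
#: ``score, pred, truth, fold``.
FoldScores = pd.DataFrame


def _fit_fold(Xt: np.ndarray, yt: np.ndarray, spec: ClassifierSpec):
    clf = spec.make()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xt, yt)
    return clf


def loocv_scores_multi(
    X: pd.DataFrame,
    y: Sequence[int],
    spec: ClassifierSpec = ClassifierSpec(),
    feature_sets: Optional[dict] = None,
    preprocess_steps: Sequence[str] = ("impute", "winsorize", "standardize"),
) -> dict:
    """Leave-one-out scores for several feature subsets sharing folds.

    Preprocessing is refitted on every training fold of the *full* metric
    table (so a patient missing one test is imputed from the others),
    then each feature set gets its own classifier on the selected
    columns.  Returns ``{name: FoldScores}``.
    """
    y = np.asarray(y, dtype=int)
    n = len(X)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 patients")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes (-1 and +1)")
    if feature_sets is None:
        feature_sets = {"all": tuple(X.columns)}
    for name, cols in feature_sets.items():
        if len(cols) == 0:
            raise ConfigurationError(f"feature set '{name}' is empty")
        missing = set(cols) - set(X.columns)
        if missing:
            raise ConfigurationError(f"feature set '{name}' names unknown metric(s) {sorted(missing)}")

    out = {
        name: {"score": np.full(n, np.nan), "ok": np.zeros(n, dtype=bool)}
        for name in feature_sets
    }
    for i in range(n):
        train = X.drop(X.index[i])
        yt = np.delete(y, i)
        if len(np.unique(yt)) < 2:
            logger.warning("fold %d: training labels are single-class; fold excluded", i)
            continue
        pm = PreprocessModel(steps=tuple(preprocess_steps)).fit(train)
        Xt = pm.transform(train)
        xq = pm.transform(X.iloc[[i]])
        for name, cols in feature_sets.items():
            kept = [c for c in cols if c in Xt.columns]
            if not kept:
                raise ConfigurationError(
                    f"feature set '{name}' lost all columns in preprocessing"
                )
            clf = _fit_fold(Xt[kept].to_numpy(), yt, spec)
            # Held-out decision values from different folds are not on a
            # common scale (each fold refits the classifier, so the
            # intercept and the weight norm wander with the training
            # composition; pooling raw values is badly anti-calibrated
            # near the null).  Each held-out value is therefore z-scored
            # against its own fold's training decision values before
            # pooling: a monotone within-fold map that makes the pooled
            # ROC well defined.
            s_train = spec.score_of(clf, Xt[kept].to_numpy())
            s_q = spec.score_of(clf, xq[kept].to_numpy())[0]
            mu, sd = float(np.mean(s_train)), float(np.std(s_train))
            out[name]["score"][i] = (s_q - mu) / (sd if sd > 0 else 1.0)
            out[name]["ok"][i] = True

    results = {}
    for name in feature_sets:
        s, ok = out[name]["score"], out[name]["ok"]
        fs = pd.DataFrame(
            {
                "score": s[ok],
                "pred": np.where(s[ok] >= 0, 1, -1),
                "truth": y[ok],
                "fold": np.flatnonzero(ok),
            },
            index=X.index[ok],
        )
        results[name] = fs
    return results


def loocv_scores(
    X: pd.DataFrame,
    y: Sequence[int],
    spec: ClassifierSpec = ClassifierSpec(),
    features: Optional[Sequence[str]] = None,
    preprocess_steps: Sequence[str] = ("impute", "winsorize", "standardize"),
) -> FoldScores:
    """Pooled held-out decision scores under LOOCV (single feature set)."""
    sets = {"_": tuple(features) if features is not None else tuple(X.columns)}
    return loocv_scores_multi(X, y, spec, sets, preprocess_steps)["_"]


# -- ROC / AUC -----------------------------------------------------------


def auc_mannwhitney(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the pairwise concordance probability P(score+ > score-),
    ties counted 1/2 — computed via midranks, identical to trapezoidal
    integration of the empirical ROC."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes to compute an AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class RocResult:
    """ROC sweep with AUC, bootstrap CI and the Youden-optimal point.
    The positive class is +1 (right side affected)."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci: Optional[tuple] = None
    oop: Optional[OperatingPoint] = None
    n_pos: int = 0
    n_neg: int = 0


def roc(fold_scores: FoldScores) -> RocResult:
    """ROC over the pooled held-out scores; AUC by trapezoidal
    integration (== Mann-Whitney concordance with ties 1/2)."""
    truth = fold_scores["truth"].to_numpy()
    scores = fold_scores["score"].to_numpy(dtype=float)
    if len(np.unique(truth)) < 2:
        raise ValueError("single-class truth: ROC undefined")
    fpr, tpr, thr = roc_curve(truth, scores, pos_label=1, drop_intermediate=False)
    result = RocResult(
        sensitivity=tpr,
        specificity=1.0 - fpr,
        thresholds=thr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_pos=int((truth == 1).sum()),
        n_neg=int((truth == -1).sum()),
    )
    return RocResult(
        **{**result.__dict__, "oop": optimal_operating_point(result)}
    )


def optimal_operating_point(roc_result: RocResult) -> OperatingPoint:
    """The sweep point maximizing Youden's J = sens + spec - 1; ties go
    to higher sensitivity, then to the lower threshold."""
    j = roc_result.sensitivity + roc_result.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    best = best[roc_result.sensitivity[best] == roc_result.sensitivity[best].max()]
    # roc_curve thresholds are decreasing, so the last candidate has the
    # lowest threshold.
    k = int(best[-1])
    return OperatingPoint(
        threshold=float(roc_result.thresholds[k]),
        sensitivity=float(roc_result.sensitivity[k]),
        specificity=float(roc_result.specificity[k]),
        youden_j=float(j[k]),
    )


def auc_ci(
    fold_scores: FoldScores, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """95% percentile-bootstrap CI for the AUC, resampling patients with
    replacement stratified by class (seeded, reproducible)."""
    truth = fold_scores["truth"].to_numpy()
    scores = fold_scores["score"].to_numpy(dtype=float)
    pos = np.flatnonzero(truth == 1)
    neg = np.flatnonzero(truth == -1)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes for a bootstrap CI")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 101])
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = auc_mannwhitney(scores[idx], truth[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def paired_bootstrap_auc_test(
    scores_a: FoldScores, scores_b: FoldScores, n_boot: int = 2000, seed: int = 0
) -> float:
    """Two-sided paired bootstrap test of AUC_a == AUC_b on the same
    patients.

    Patients are resampled with replacement (paired across the two score
    sets); p = 2 * min(P(diff <= 0), P(diff >= 0)) with zero differences
    counted half on each side.  Single-class resamples are redrawn.
    """
    if not scores_a.index.equals(scores_b.index):
        raise ValueError("paired test requires identical patients in both score sets")
    ta = scores_a["truth"].to_numpy()
    if not np.array_equal(ta, scores_b["truth"].to_numpy()):
        raise ValueError("paired test requires identical truth labels")
    sa = scores_a["score"].to_numpy(dtype=float)
    sb = scores_b["score"].to_numpy(dtype=float)
    n = len(ta)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 202])
    diffs = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            t = ta[idx]
            if (t == 1).any() and (t == -1).any():
                break
            redraws += 1
        diffs[b] = auc_mannwhitney(sa[idx], t) - auc_mannwhitney(sb[idx], t)
    if redraws:
        logger.info("paired_bootstrap_auc_test: redrew %d single-class resample(s)", redraws)
    half_zero = 0.5 * np.mean(diffs == 0.0)
    p_le = np.mean(diffs < 0.0) + half_zero
    p_ge = np.mean(diffs > 0.0) + half_zero
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# -- feature ranking and model building ----------------------------------


def svm_feature_ranking(
    X: pd.DataFrame,
    y: Sequence[int],
    spec: ClassifierSpec = ClassifierSpec(family="linear_svm"),
    preprocess_steps: Sequence[str] = ("impute", "winsorize", "standardize"),
) -> tuple[list, pd.Series]:
    """Rank metrics by |weight| of a linear SVM fitted once on the whole
    (preprocessed, standardized) cohort.  Returns (ordered metric names,
    signed weights)."""
    y = np.asarray(y, dtype=int)
    pm = PreprocessModel(steps=tuple(preprocess_steps)).fit(X)
    Xt = pm.transform(X)
    clf = spec.make()
    if not isinstance(clf, LinearSVC):
        clf = LinearSVC(C=spec.svm_cost, max_iter=10_000, tol=spec.tol, random_state=0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Xt.to_numpy(), y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise ConvergenceError(
                f"linear SVM did not converge after {clf.n_iter_} iterations"
            )
    weights = pd.Series(clf.coef_[0], index=Xt.columns, name="svm_weight")
    order = weights.abs().sort_values(ascending=False, kind="stable").index.tolist()
    return order, weights


@dataclass(frozen=True)
class StepwiseTrace:
    """Cumulative multivariate AUC along an SVM-weight feature ordering."""

    metrics: list
    aucs: list
    cis: list
    plateau_k: int  # smallest k whose AUC is within 0.005 of the maximum

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric_added": self.metrics,
                "auc": self.aucs,
                "ci_lo": [c[0] for c in self.cis],
                "ci_hi": [c[1] for c in self.cis],
            },
            index=pd.RangeIndex(1, len(self.metrics) + 1, name="k"),
        )


def stepwise_auc(
    X: pd.DataFrame,
    y: Sequence[int],
    ranking: Sequence[str],
    spec: ClassifierSpec = ClassifierSpec(),
    n_boot: int = 2000,
    seed: int = 0,
) -> StepwiseTrace:
    """Cumulative LOOCV AUC over the top-k metrics of ``ranking``,
    k = 1..K, with a percentile-bootstrap CI at every step."""
    ranking = list(ranking)
    sets = {f"k{k}": tuple(ranking[:k]) for k in range(1, len(ranking) + 1)}
    scored = loocv_scores_multi(X, y, spec, sets)
    aucs, cis = [], []
    for k in range(1, len(ranking) + 1):
        fs = scored[f"k{k}"]
        aucs.append(roc(fs).auc)
        cis.append(auc_ci(fs, n_boot=n_boot, seed=seed + k))
    plateau = min(k for k in range(1, len(ranking) + 1) if aucs[k - 1] >= max(aucs) - 0.005)
    return StepwiseTrace(metrics=ranking, aucs=aucs, cis=cis, plateau_k=plateau)


def grouped_models(
    X: pd.DataFrame,
    y: Sequence[int],
    groups: Optional[dict] = None,
    spec: ClassifierSpec = ClassifierSpec(),
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Multivariate LOOCV ROC per named metric group (default: the
    canal-proxy vs otolith-proxy contrast)."""
    groups = dict(groups) if groups is not None else dict(METRIC_GROUPS)
    scored = loocv_scores_multi(X, y, spec, groups)
    out = {}
    for name, fs in scored.items():
        r = roc(fs)
        out[name] = RocResult(**{**r.__dict__, "ci": auc_ci(fs, n_boot=n_boot, seed=seed)})
    return out


def compare_classifiers(
    X: pd.DataFrame,
    y: Sequence[int],
    features: Optional[Sequence[str]] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic regression, Gaussian naive Bayes and linear SVM side by
    side on identical LOOCV folds; returns per-family AUC, CI and
    held-out accuracy."""
    rows = {}
    for family in ("logistic", "naive_bayes", "linear_svm"):
        fs = loocv_scores(X, y, ClassifierSpec(family=family), features=features)
        lo, hi = auc_ci(fs, n_boot=n_boot, seed=seed)
        rows[family] = {
            "auc": roc(fs).auc,
            "ci_lo": lo,
            "ci_hi": hi,
            "accuracy": float((fs["pred"] == fs["truth"]).mean()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
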