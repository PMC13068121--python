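"""Model/Results front end for affected-side prediction.

``AffectedSideModel`` bundles a canonical asymmetry-feature table with
MRI-given side labels; ``fit()`` runs the leave-one-out cross-validated
classifier and returns an ``AffectedSideResults`` object carrying the
pooled held-out scores, the ROC, the AUC with its bootstrap confidence
interval, the optimal operating point and a text ``summary()``.
Feature ranking, the stepwise AUC trace, grouped canal/otolith models
and the classifier comparison hang off the model; plotting hangs off
the results.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import predict
from .asymmetry import METRICS, asymmetry_table
from .bias import correct_records, estimate_offset
from .predict import ClassifierSpec, RocResult

__all__ = ["AffectedSideModel", "AffectedSideResults"]


class AffectedSideModel:
    """Predict the affected side (-1 left / +1 right) from canonical
    asymmetry metrics.

    Parameters
    ----------
    features : DataFrame
        Per-patient canonical asymmetry metrics (positive = right side
        affected); may contain missing values, which are imputed within
        cross-validation folds.
    labels : sequence of -1/+1
        MRI-given affected side per patient.
    classifier : {'logistic', 'naive_bayes', 'linear_svm'}
    n_boot : int
        Bootstrap resamples for confidence intervals.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence[int],
        classifier: str = "logistic",
        n_boot: int = 2000,
    ):
        labels = np.asarray(labels, dtype=int)
        if len(labels) != len(features):
            raise ValueError("labels and features disagree in length")
        self.features = features
        self.labels = labels
        self.spec = ClassifierSpec(family=classifier)
        self.n_boot = n_boot

    @classmethod
    def from_records(
        cls,
        patients,
        controls=None,
        correct_bias: bool = True,
        offset_side: str = "left",
        **kwargs,
    ) -> "AffectedSideModel":
        """Build a model from raw measurement records.

        When ``controls`` are given and ``correct_bias`` is true, the
        monocular-vHIT gain offset is estimated from the comparison
        group and removed from the patient gains before the asymmetry
        metrics are computed.
        """
        gains = None
        if correct_bias:
            if controls is None:
                raise ValueError("bias correction requires a comparison group")
            offset = estimate_offset(controls)
            gains = correct_records(patients, offset, side=offset_side)
        X = asymmetry_table(patients, gains=gains, canonical=True)
        y = [r.true_side for r in patients]
        if any(s is None for s in y):
            raise ValueError("every patient record needs a true side label")
        return cls(X, y, **kwargs)

    def fit(
        self, metrics: Optional[Sequence[str]] = None, seed: int = 0
    ) -> "AffectedSideResults":
        """Run LOOCV (preprocessing refitted per fold) on the chosen
        metrics (default: all) and evaluate the pooled held-out ROC."""
        fs = predict.loocv_scores(self.features, self.labels, self.spec, features=metrics)
        r = predict.roc(fs)
        ci = predict.auc_ci(fs, n_boot=self.n_boot, seed=seed)
        r = RocResult(**{**r.__dict__, "ci": ci})
        used = tuple(metrics) if metrics is not None else tuple(self.features.columns)
        return AffectedSideResults(self, fs, r, used, seed)

    # -- companion analyses ---------------------------------------------

    def univariate(self, seed: int = 0) -> pd.DataFrame:
        """Per-metric LOOCV AUC with CI, on shared folds."""
        sets = {m: (m,) for m in self.features.columns}
        scored = predict.loocv_scores_multi(self.features, self.labels, self.spec, sets)
        rows = {}
        for m, fs in scored.items():
            lo, hi = predict.auc_ci(fs, n_boot=self.n_boot, seed=seed)
            rows[m] = {"auc": predict.roc(fs).auc, "ci_lo": lo, "ci_hi": hi}
        return pd.DataFrame.from_dict(rows, orient="index")

    def rank_features(self):
        """SVM-|weight| feature ranking on the whole cohort."""
        return predict.svm_feature_ranking(self.features, self.labels)

    def stepwise(self, ranking: Optional[Sequence[str]] = None, seed: int = 0):
        """Cumulative multivariate AUC along the (SVM-weight) ranking."""
        if ranking is None:
            ranking, _ = self.rank_features()
        return predict.stepwise_auc(
            self.features, self.labels, ranking, self.spec, n_boot=self.n_boot, seed=seed
        )

    def grouped(self, groups: Optional[dict] = None, seed: int = 0) -> dict:
        """Canal-proxy vs otolith-proxy multivariate models."""
        return predict.grouped_models(
            self.features, self.labels, groups, self.spec, n_boot=self.n_boot, seed=seed
        )

    def compare_classifiers(self, seed: int = 0) -> pd.DataFrame:
        return predict.compare_classifiers(
            self.features, self.labels, n_boot=self.n_boot, seed=seed
        )


class AffectedSideResults:
    """LOOCV results: held-out scores, ROC, AUC (95% CI), operating point."""

    def __init__(self, model, fold_scores, roc_result, metrics, seed):
        self.model = model
        self.fold_scores = fold_scores
        self.roc_ = roc_result
        self.metrics = metrics
        self.seed = seed

    @property
    def auc(self) -> float:
        return self.roc_.auc

    @property
    def ci(self):
        return self.roc_.ci

    @property
    def oop(self):
        return self.roc_.oop

    @property
    def accuracy(self) -> float:
        fs = self.fold_scores
        return float((fs["pred"] == fs["truth"]).mean())

    def summary(self) -> str:
        o = self.oop
        lines = [
            "Affected-side prediction (LOOCV)",
            "=" * 44,
            f"classifier:        {self.model.spec.family}",
            f"metrics:           {', '.join(self.metrics)}",
            f"n patients:        {len(self.fold_scores)}"
            f"  (right {self.roc_.n_pos} / left {self.roc_.n_neg})",
            f"positive class:    +1 (right side affected)",
            f"AUC:               {self.auc:.3f}",
            f"95% CI (bootstrap): ({self.ci[0]:.3f}, {self.ci[1]:.3f})"
            f"  [{self.model.n_boot} resamples, seed {self.seed}]",
            f"held-out accuracy: {self.accuracy:.3f}",
            f"operating point:   sens {o.sensitivity:.2f}, spec {o.specificity:.2f},"
            f" J {o.youden_j:.2f} @ thr {o.threshold:.3f}",
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None, label: Optional[str] = None):
        """Plot the ROC curve (1-specificity vs sensitivity) with the
        optimal operating point marked; returns the axes."""
        import matplotlib

        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(4.5, 4.5))
        r = self.roc_
        lbl = label or f"{self.model.spec.family} (AUC {r.auc:.2f})"
        ax.plot(1.0 - r.specificity, r.sensitivity, label=lbl)
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
        ax.plot(1.0 - r.oop.specificity, r.oop.sensitivity, "o", mfc="none", color="k")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", frameon=False)
        return ax
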