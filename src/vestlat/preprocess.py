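"""Fold-aware cleaning of the per-patient asymmetry-metric table.

The cleaning steps — 1-nearest-neighbor imputation, mean +/- 2 SD
winsorization, range normalization and z-scoring — are all *fitted on
training rows only* and then applied to held-out rows, so that under
leave-one-out cross-validation no information from the held-out patient
leaks into the fold's statistics.

Step semantics
--------------
* **impute**: each missing entry is replaced by the corresponding value
  of the single nearest training row.  Distance is Euclidean over the
  mutually observed columns, rescaled by ``sqrt(n_columns / n_shared)``;
  exact ties go to the smallest training-row position.
* **winsorize**: entries beyond the training mean +/- 2 * SD (sample SD)
  are replaced by the most extreme *training value* still inside the
  bound in the same direction (falling back to the bound itself when no
  in-range training value exists on that side).
* **normalize**: each entry is divided by the training range (max - min)
  of its column (descriptive path).
* **standardize**: classical (x - mean)/SD z-scoring with training
  statistics (classifier path).

Columns with zero training range/SD are dropped with a warning.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ImputationError

__all__ = [
    "PreprocessModel",
    "impute_1nn",
    "winsorize",
    "normalize_range",
    "standardize",
]

logger = logging.getLogger("vestlat")

_KNOWN_STEPS = ("impute", "winsorize", "normalize", "standardize")


def _nn_distances(query: np.ndarray, donors: np.ndarray) -> np.ndarray:
    """Masked Euclidean distances from one query row to every donor row.

    Only columns observed in *both* rows contribute; the squared distance
    is rescaled by n_columns/n_shared.  Rows sharing no column get +inf.
    """
    p = query.shape[0]
    q_obs = ~np.isnan(query)
    d_obs = ~np.isnan(donors)
    shared = q_obs & d_obs
    n_shared = shared.sum(axis=1)
    diff = np.where(shared, donors - query, 0.0)
    sq = np.einsum("ij,ij->i", diff, diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.sqrt(np.where(n_shared > 0, sq * (p / np.maximum(n_shared, 1)), np.inf))
    dist[n_shared == 0] = np.inf
    return dist


def _impute_matrix(
    target: np.ndarray, donors: np.ndarray, leave_self_out: bool = False
) -> np.ndarray:
    """1-NN imputation of ``target`` using ``donors`` as the training
    snapshot.  With ``leave_self_out`` row i never donates to itself
    (used when imputing the training matrix during fit).  Each missing
    entry takes the value of the nearest donor *observed in that column*.
    """
    out = target.copy()
    for i in range(target.shape[0]):
        row = target[i]
        miss = np.isnan(row)
        if not miss.any():
            continue
        if not (~miss).any():
            raise ImputationError(f"row {i} has no observed value")
        dist = _nn_distances(row, donors)
        if leave_self_out:
            dist = dist.copy()
            dist[i] = np.inf
        for j in np.flatnonzero(miss):
            has_col = ~np.isnan(donors[:, j])
            cand = np.where(has_col, dist, np.inf)
            k = int(np.argmin(cand))  # argmin -> smallest index on ties
            if not np.isfinite(cand[k]):
                raise ImputationError(
                    f"no training row shares an observed column (and column {j}) with row {i}"
                )
            out[i, j] = donors[k, j]
    return out


class PreprocessModel:
    """Training-fold snapshot of all cleaning statistics.

    Parameters
    ----------
    steps : sequence of {'impute', 'winsorize', 'normalize', 'standardize'}
        Applied in the given order by :meth:`transform`.  The default is
        the classifier path; the descriptive path replaces 'standardize'
        with 'normalize'.
    """

    def __init__(self, steps: Sequence[str] = ("impute", "winsorize", "standardize")):
        unknown = set(steps) - set(_KNOWN_STEPS)
        if unknown:
            raise ValueError(f"unknown preprocessing step(s): {sorted(unknown)}")
        self.steps = tuple(steps)
        self.fitted_ = False

    # -- fitting ---------------------------------------------------------

    def fit(self, X: pd.DataFrame) -> "PreprocessModel":
        """Fit every step's statistics on the training rows of ``X``."""
        if len(X) == 0:
            raise ValueError("cannot fit on an empty training matrix")
        self.columns_ = list(X.columns)
        train = X.to_numpy(dtype=float)

        if "impute" in self.steps:
            train = _impute_matrix(train, train, leave_self_out=True)
        self.train_imputed_ = train
        self.kept_columns_ = list(self.columns_)

        if "winsorize" in self.steps:
            mean = np.nanmean(train, axis=0)
            sd = np.nanstd(train, axis=0, ddof=1) if len(train) > 1 else np.zeros(train.shape[1])
            self.winsor_lower_ = mean - 2.0 * sd
            self.winsor_upper_ = mean + 2.0 * sd
            self.winsor_low_repl_ = np.empty(train.shape[1])
            self.winsor_high_repl_ = np.empty(train.shape[1])
            for j in range(train.shape[1]):
                col = train[:, j]
                col = col[~np.isnan(col)]
                inside_hi = col[col <= self.winsor_upper_[j]]
                inside_lo = col[col >= self.winsor_lower_[j]]
                if inside_hi.size:
                    self.winsor_high_repl_[j] = inside_hi.max()
                else:  # pragma: no cover - needs an empty acceptable range
                    self.winsor_high_repl_[j] = self.winsor_upper_[j]
                    logger.warning("winsorize: no in-range training value below the upper bound")
                if inside_lo.size:
                    self.winsor_low_repl_[j] = inside_lo.min()
                else:  # pragma: no cover
                    self.winsor_low_repl_[j] = self.winsor_lower_[j]
                    logger.warning("winsorize: no in-range training value above the lower bound")
            train = self._winsorize_array(train)
        self.train_winsorized_ = train

        if "normalize" in self.steps:
            rng = np.nanmax(train, axis=0) - np.nanmin(train, axis=0)
            self.range_ = rng
            drop = [c for c, r in zip(self.columns_, rng) if not r > 0]
            if drop:
                logger.warning("normalize_range: dropping zero-range column(s) %s", drop)
                self.kept_columns_ = [c for c in self.kept_columns_ if c not in drop]

        if "standardize" in self.steps:
            self.std_mean_ = np.nanmean(train, axis=0)
            self.std_sd_ = (
                np.nanstd(train, axis=0, ddof=1) if len(train) > 1 else np.zeros(train.shape[1])
            )
            drop = [c for c, s in zip(self.columns_, self.std_sd_) if not s > 0]
            if drop:
                logger.warning("standardize: dropping zero-variance column(s) %s", drop)
                self.kept_columns_ = [c for c in self.kept_columns_ if c not in drop]

        self.fitted_ = True
        return self

    # -- transforming ----------------------------------------------------

    def _check(self, X: pd.DataFrame):
        if not self.fitted_:
            raise ValueError("PreprocessModel is not fitted")
        if list(X.columns) != self.columns_:
            raise ValueError("column mismatch between fit and transform")

    def _winsorize_array(self, a: np.ndarray) -> np.ndarray:
        out = a.copy()
        hi = out > self.winsor_upper_
        lo = out < self.winsor_lower_
        out = np.where(hi, np.broadcast_to(self.winsor_high_repl_, out.shape), out)
        out = np.where(lo, np.broadcast_to(self.winsor_low_repl_, out.shape), out)
        return out

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Apply the fitted steps, in order, to ``X`` (training or
        held-out rows); returns only the retained columns."""
        self._check(X)
        a = X.to_numpy(dtype=float)
        for step in self.steps:
            if step == "impute":
                a = _impute_matrix(a, self.train_imputed_)
            elif step == "winsorize":
                a = self._winsorize_array(a)
            elif step == "normalize":
                with np.errstate(divide="ignore", invalid="ignore"):
                    a = a / self.range_
            elif step == "standardize":
                with np.errstate(divide="ignore", invalid="ignore"):
                    a = (a - self.std_mean_) / self.std_sd_
        out = pd.DataFrame(a, index=X.index, columns=self.columns_)
        return out[self.kept_columns_]

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


# -- functional forms of the individual operations -----------------------


def impute_1nn(X: pd.DataFrame, model: PreprocessModel) -> pd.DataFrame:
    """1-NN imputation of ``X`` against the model's training snapshot."""
    model._check(X)
    a = _impute_matrix(X.to_numpy(dtype=float), model.train_imputed_)
    return pd.DataFrame(a, index=X.index, columns=model.columns_)


def winsorize(X: pd.DataFrame, model: PreprocessModel) -> pd.DataFrame:
    """Replace out-of-bound entries by the most extreme in-range training
    value in the same direction."""
    model._check(X)
    a = model._winsorize_array(X.to_numpy(dtype=float))
    return pd.DataFrame(a, index=X.index, columns=model.columns_)


def normalize_range(X: pd.DataFrame, model: PreprocessModel) -> pd.DataFrame:
    """Divide each column by its training range (max - min)."""
    model._check(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = X.to_numpy(dtype=float) / model.range_
    return pd.DataFrame(a, index=X.index, columns=model.columns_)[model.kept_columns_]


def standardize(X: pd.DataFrame, model: PreprocessModel) -> pd.DataFrame:
    """Z-score each column with its training mean and SD."""
    model._check(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (X.to_numpy(dtype=float) - model.std_mean_) / model.std_sd_
    return pd.DataFrame(a, index=X.index, columns=model.columns_)[model.kept_columns_]
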