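"""End-to-end orchestration: simulate/read -> bias-correct -> asymmetry
metrics -> descriptives -> LOOCV prediction -> report bundle.

Stage order: raw vHIT gains are bias-corrected globally (the comparison
group is never classified, so its offset is estimated once), asymmetry
metrics are computed from the corrected gains, and the metric-table
cleaning (imputation, winsorization, standardization) happens inside
every cross-validation fold during classification.

Every output embeds the resolved configuration hash and seed; two runs
with the same configuration are identical (timestamps are confined to
the log).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .asymmetry import METRICS, asymmetry_table
from .bias import correct_records, estimate_offset, left_right_ttests
from .config import RunConfig
from .descriptives import describe_cohort
from .exceptions import StageError
from .io import read_cohort, write_cohort
from .model import AffectedSideModel
from .simulate import generate_cohort, generate_controls

__all__ = ["run_pipeline"]

logger = logging.getLogger("vestlat")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the in-memory bundle (tables and JSON-serializable results).
    On a stage failure, partially written outputs are removed and a
    :class:`StageError` naming the stage is raised.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, index=True):
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)

    def save_json(obj, name: str):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True))
        written.append(p)

    meta = {"config_hash": config.hash(), "seed": config.seed}
    try:
        bundle = _run(config, save_csv, save_json, meta)
        save_json({**meta, "config": json.loads(config.to_json())}, "config_resolved.json")
        (out / "run.log").write_text(
            f"vestlat pipeline\nconfig_hash: {meta['config_hash']}\nseed: {config.seed}\n"
        )
        return bundle
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, save_csv, save_json, meta) -> dict:
    # -- input stage -----------------------------------------------------
    @_stage("input")
    def load():
        if config.simulate is not None:
            sim = config.simulate.model_copy(update={"seed": config.seed})
            pats = generate_cohort(sim)
            ctrls = generate_controls(sim)
        else:
            pats = read_cohort(config.patients_csv)
            ctrls = read_cohort(config.controls_csv) if config.controls_csv else None
        if any(r.true_side is None for r in pats):
            raise ValueError("patient table has records without a true_side label")
        return pats, ctrls

    patients, controls = load()

    # -- bias correction -------------------------------------------------
    @_stage("bias_correction")
    def correct():
        if not config.correct_bias:
            return None, None, None, None
        if controls is None:
            raise ValueError("bias correction enabled but no comparison group given")
        offset = estimate_offset(controls)
        pre = left_right_ttests(patients)
        gains = correct_records(patients, offset, side=config.offset_side)
        post = left_right_ttests(gains)
        return offset, gains, pre, post

    offset, corrected_gains, ttests_pre, ttests_post = correct()

    # -- asymmetry metrics -----------------------------------------------
    @_stage("asymmetry_metrics")
    def metrics():
        X = asymmetry_table(patients, gains=corrected_gains, canonical=True)
        y = np.array([r.true_side for r in patients], dtype=int)
        return X, y

    X, y = metrics()
    save_csv(X, "metrics.csv")

    # -- descriptives ----------------------------------------------------
    @_stage("descriptives")
    def describe():
        table, (r, p) = describe_cohort(X, y)
        return table, r, p

    desc, pearson_r, pearson_p = describe()
    save_csv(desc, "descriptives.csv")
    if ttests_pre is not None:
        save_csv(ttests_pre, "ttests_pre_correction.csv")
        save_csv(ttests_post, "ttests_post_correction.csv")

    # -- prediction ------------------------------------------------------
    @_stage("side_prediction")
    def predict_stage():
        model = AffectedSideModel(X, y, classifier=config.classifier, n_boot=config.n_boot)
        uni = model.univariate(seed=config.seed)
        ranking, weights = model.rank_features()
        trace = model.stepwise(ranking, seed=config.seed)
        grouped = model.grouped(seed=config.seed)
        comparison = model.compare_classifiers(seed=config.seed)
        results = model.fit(seed=config.seed)
        return model, results, uni, ranking, weights, trace, grouped, comparison

    (model, results, uni, ranking, weights, trace, grouped, comparison) = predict_stage()

    save_csv(uni, "univariate_auc.csv")
    save_csv(trace.as_frame(), "stepwise_auc.csv")
    save_csv(comparison, "classifier_comparison.csv")
    save_csv(results.fold_scores, "heldout_scores.csv")
    save_json(
        {
            **meta,
            "positive_class": "+1 (right side affected)",
            "full_model_auc": results.auc,
            "full_model_ci": list(results.ci),
            "oop": results.oop.__dict__,
            "univariate_auc": uni["auc"].to_dict(),
            "svm_ranking": list(ranking),
            "svm_weights": weights.to_dict(),
            "stepwise_auc": trace.aucs,
            "stepwise_plateau_k": trace.plateau_k,
            "grouped_auc": {k: v.auc for k, v in grouped.items()},
            "grouped_ci": {k: list(v.ci) for k, v in grouped.items()},
            "pearson_r_asymmetry_vs_correspondence": pearson_r,
            "pearson_p": pearson_p,
            "offset": None
            if offset is None
            else {
                "lateral": offset.lateral,
                "anterior": offset.anterior,
                "posterior": offset.posterior,
            },
        },
        "results.json",
    )

    return {
        "patients": patients,
        "controls": controls,
        "offset": offset,
        "ttests_pre": ttests_pre,
        "ttests_post": ttests_post,
        "features": X,
        "labels": y,
        "descriptives": desc,
        "pearson": (pearson_r, pearson_p),
        "model": model,
        "results": results,
        "univariate": uni,
        "ranking": ranking,
        "svm_weights": weights,
        "stepwise": trace,
        "grouped": grouped,
        "classifier_comparison": comparison,
    }
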