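"""Repeated stratified cross-validation harness and metric reporting.

Each repetition shuffles the cohort into k class-stratified folds; per fold
the model is standardised, fitted and threshold-aligned on the training
blocks only, then scored on the held-out block.  The k held-out blocks are
pooled into one per-repeat ROC/AUC and one per-repeat confusion matrix, so a
run with ``n_repeats`` repetitions yields ``n_repeats`` values of each metric
(accuracy, precision, recall, F-measure, AUC), summarised by mean, sample SD
and a 95% confidence interval for the mean.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import model as model_mod
from . import select as select_mod
from .octfeat import CLINICAL_FEATURES, LABEL_COLUMN
from .model import ModelBundle, PipelineConfig, align_threshold, fit_logistic, standardize
from .select import encode_numeric

logger = logging.getLogger(__name__)

__all__ = [
    "CVReport",
    "StudyResult",
    "stratified_kfold_indices",
    "rank_auc",
    "confusion_metrics",
    "binary_metrics",
    "confidence_interval",
    "repeated_cv",
    "run_study",
    "control_experiment",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f_measure", "auc")


# --------------------------------------------------------------------------
# Fold construction
# --------------------------------------------------------------------------


def stratified_kfold_indices(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded stratified fold assignment; returns fold ids 0..k-1 per record.

    Each class is shuffled and dealt into k folds whose per-class counts
    differ by at most one (the first ``n_c mod k`` folds take the extra
    record), e.g. 32/11 at k=5 gives per-fold counts (7,7,6,6,6)/(3,2,2,2,2).
    """
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has {len(idx)} members, fewer than k={k}")
        idx = rng.permutation(idx)
        n_c = len(idx)
        sizes = [n_c // k + (1 if f < n_c % k else 0) for f in range(k)]
        start = 0
        for f, s in enumerate(sizes):
            folds[idx[start:start + s]] = f
            start += s
    return folds


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


def rank_auc(y_true, scores) -> float:
    """AUC by the rank (Mann–Whitney) formulation with half credit for ties."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    """Full-threshold-sweep ROC as (fpr, tpr) arrays from (0,0) to (1,1)."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, len(y) - 1]
    tpr = np.r_[0.0, tp[cut] / max(y.sum(), 1)]
    fpr = np.r_[0.0, fp[cut] / max((~y).sum(), 1)]
    return fpr, tpr


def confusion_metrics(y_true, predictions) -> dict[str, float]:
    """Accuracy / precision / recall / F from binary predictions.

    Zero predicted positives make precision undefined; it is reported as 1
    (the conservative-threshold sentinel convention) with a logged flag.
    """
    y = np.asarray(y_true).astype(bool)
    pred = np.asarray(predictions).astype(bool)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    if tp + fp == 0:
        logger.info("zero predicted positives: precision reported as 1")
        precision = 1.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {
        "accuracy": float((pred == y).mean()),
        "precision": float(precision),
        "recall": float(recall),
        "f_measure": float(f),
    }


def binary_metrics(y_true, scores, threshold: float) -> dict:
    """All scalar metrics at a threshold plus the ROC sweep."""
    y = np.asarray(y_true).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    s = np.asarray(scores, dtype=float)
    out = confusion_metrics(y, s >= threshold)
    out["auc"] = rank_auc(y, s)
    fpr, tpr = roc_points(y, s)
    out["roc"] = (fpr, tpr)
    return out


def confidence_interval(
    values=None, mean: float | None = None, sd: float | None = None,
    n: int | None = None, method: str = "t",
) -> tuple[float, float]:
    """95% confidence interval for a mean.

    Either pass the raw ``values`` or the summary triple ``(mean, sd, n)``.
    The default uses the t quantile with n-1 df: mean +/- t_{0.975,n-1} sd/sqrt(n).
    """
    if values is not None:
        values = np.asarray(values, dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        n = len(values)
    if n is None or n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    crit = float(stats.t.ppf(0.975, n - 1)) if method == "t" else float(stats.norm.ppf(0.975))
    half = crit * sd / math.sqrt(n)
    return (mean - half, mean + half)


# --------------------------------------------------------------------------
# Repeated CV
# --------------------------------------------------------------------------

_ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class CVReport:
    """Per-repeat metrics, their summaries, and the coefficient report."""

    variables: tuple[str, ...]
    per_repeat: dict[str, np.ndarray]
    summaries: dict[str, dict]
    mean_roc: tuple[np.ndarray, np.ndarray]
    coefficient_report: dict[str, dict]
    c_value: float
    thresholds: np.ndarray
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "per_repeat": {k: v.tolist() for k, v in self.per_repeat.items()},
            "summaries": self.summaries,
            "mean_roc": {"fpr": self.mean_roc[0].tolist(), "tpr": self.mean_roc[1].tolist()},
            "coefficient_report": self.coefficient_report,
            "c_value": self.c_value,
            "thresholds": self.thresholds.tolist(),
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _fit_fold(X_train, y_train, X_test, c_value, feature_names, rule):
    """Train-side computation for one fold; sees no test labels at all."""
    z_train, mu, sd = standardize(X_train)
    bundle = fit_logistic(z_train, y_train, c_value, feature_names=feature_names,
                          means=mu, sds=sd)
    bundle.threshold = align_threshold(bundle.decision_scores(X_train), y_train, rule=rule)
    return bundle, bundle.decision_scores(X_test)


def repeated_cv(
    table: pd.DataFrame, variables, config: PipelineConfig, c_value: float
) -> CVReport:
    """n_repeats seeded repetitions of stratified k-fold CV.

    Per repetition the k held-out blocks are pooled into one ROC/AUC and one
    confusion matrix; each fold's threshold is aligned on its training blocks
    only and applied unchanged to its test block.  Deterministic given the
    master seed in ``config``.
    """
    config.validate()
    variables = tuple(variables)
    X = encode_numeric(table, variables).to_numpy()
    y = (table[LABEL_COLUMN] == config.positive_class).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both groups must be present")
    ss = np.random.SeedSequence([config.seed, 0xCF])
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_repeats)]
    per_repeat = {name: np.empty(config.n_repeats) for name in METRIC_NAMES}
    tprs = []
    thresholds = []
    bundles: list[ModelBundle] = []
    for rep, rep_seed in enumerate(rep_seeds):
        folds = stratified_kfold_indices(y, k=config.k_folds, seed=rep_seed)
        scores = np.empty(len(y))
        preds = np.empty(len(y), dtype=bool)
        for f in range(config.k_folds):
            test = folds == f
            train = ~test
            bundle, test_scores = _fit_fold(
                X[train], y[train], X[test], c_value, variables, config.alignment_rule
            )
            scores[test] = test_scores
            preds[test] = test_scores >= bundle.threshold
            thresholds.append(bundle.threshold)
            bundles.append(bundle)
        m = confusion_metrics(y, preds)
        m["auc"] = rank_auc(y, scores)
        for name in METRIC_NAMES:
            per_repeat[name][rep] = m[name]
        fpr, tpr = roc_points(y, scores)
        tprs.append(np.interp(_ROC_GRID, fpr, tpr))
    summaries = {}
    for name in METRIC_NAMES:
        vals = per_repeat[name]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        ci = (
            confidence_interval(mean=mean, sd=sd, n=len(vals), method=config.ci_method)
            if len(vals) > 1
            else (mean, mean)
        )
        summaries[name] = {"mean": mean, "sd": sd, "ci": ci}
    coefficient_report = (
        model_mod.collect_coefficients(bundles, ci_method=config.ci_method)
        if len(bundles) >= 2
        else {}
    )
    return CVReport(
        variables=variables,
        per_repeat=per_repeat,
        summaries=summaries,
        mean_roc=(_ROC_GRID.copy(), np.mean(tprs, axis=0)),
        coefficient_report=coefficient_report,
        c_value=float(c_value),
        thresholds=np.asarray(thresholds),
        config=config.to_dict(),
        seed=config.seed,
    )


# --------------------------------------------------------------------------
# Full study orchestration
# --------------------------------------------------------------------------


@dataclass
class StudyResult:
    """Selection outcome, fixed hyperparameter and the CV report."""

    selection: select_mod.SelectionResult
    c_star: float
    c_histogram: dict[float, int]
    report: CVReport
    final_model: ModelBundle | None = None


def run_study(table: pd.DataFrame, config: PipelineConfig, features=None) -> StudyResult:
    """Selection -> hyperparameter fixing -> repeated CV, optionally on a
    feature subset (used by the clinical-only control experiment)."""
    config.validate()
    work = table if features is None else table[list(features) + [LABEL_COLUMN]]
    selection = select_mod.select_features(
        work, alpha=config.alpha, r2_threshold=config.r2_threshold
    )
    variables = selection.final_variables
    logger.info("selected explanatory variables: %s", variables)
    X = encode_numeric(table, variables).to_numpy()
    y = (table[LABEL_COLUMN] == config.positive_class).to_numpy()
    c_star, hist = model_mod.tune_hyperparameter(X, y, config)
    report = repeated_cv(table, variables, config, c_star)
    # final bundle trained on the full cohort at the fixed constant
    z, mu, sd = standardize(X)
    final = fit_logistic(z, y, c_star, feature_names=tuple(variables), means=mu, sds=sd)
    final.threshold = align_threshold(final.decision_scores(X), y, rule=config.alignment_rule)
    return StudyResult(selection=selection, c_star=c_star, c_histogram=hist,
                       report=report, final_model=final)


def control_experiment(table: pd.DataFrame, config: PipelineConfig) -> StudyResult:
    """The clinical-information-only control: the identical pipeline restricted
    to the patient-background features (no OCT morphometry)."""
    missing = [f for f in CLINICAL_FEATURES if f not in table]
    if missing:
        raise ValueError(f"table lacks clinical features: {missing}")
    return run_study(table, config, features=list(CLINICAL_FEATURES))
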