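"""Penalised logistic-regression prognosis model.

The classifier predicts the poor-prognosis group (decimal BCVA < 0.7 at six
months, the positive class) from z-scored explanatory variables, so the
fitted weights are standard regression coefficients directly comparable
across features.  The L2 regularisation constant is not tuned per split but
*fixed by frequency*: the per-repeat best constant (by cross-validated AUC)
is recorded over many repeated stratified CV pre-tests and the modal value is
frozen for the final evaluation.  The decision threshold is aligned on the
training data so that precision >= recall — a deliberately conservative
operating point that avoids discouraging patients with a false poor-prognosis
call — by maximising F-measure over the feasible thresholds.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ModelBundle",
    "assign_group",
    "logmar_from_decimal",
    "decimal_from_logmar",
    "standardize",
    "fit_logistic",
    "tune_hyperparameter",
    "align_threshold",
    "collect_coefficients",
]

DEFAULT_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    The BCVA discrimination threshold is 0.15 logMAR (decimal ~0.7): patients
    at or above decimal 0.7 are Group A (good prognosis), below it Group B
    (poor prognosis, the positive class).
    """

    positive_class: str = "B"
    bcva_threshold_decimal: float = 0.7
    bcva_threshold_logmar: float = 0.15
    alpha: float = 0.05
    r2_threshold: float = 0.9
    k_folds: int = 5
    n_repeats: int = 100
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    tuning_objective: str = "auc"  # one of auc, f1, accuracy
    alignment_rule: str = "precision"  # precision >= recall; or "accuracy"
    ci_method: str = "t"  # or "z"
    seed: int = 0

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid must be non-empty and positive")
        if self.tuning_objective not in ("auc", "f1", "accuracy"):
            raise ValueError(f"unknown tuning objective {self.tuning_objective!r}")
        if self.alignment_rule not in ("precision", "accuracy"):
            raise ValueError(f"unknown alignment rule {self.alignment_rule!r}")
        if self.ci_method not in ("t", "z"):
            raise ValueError("ci_method must be 't' or 'z'")
        if not 0 < self.alpha < 1 or not 0 < self.r2_threshold < 1:
            raise ValueError("alpha and r2_threshold must lie in (0, 1)")
        implied = round(-math.log10(self.bcva_threshold_decimal), 2)
        if abs(implied - self.bcva_threshold_logmar) > 0.005:
            raise ValueError(
                f"decimal threshold {self.bcva_threshold_decimal} and logMAR threshold "
                f"{self.bcva_threshold_logmar} are inconsistent (-log10 gives {implied})"
            )

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "bcva_threshold_decimal": self.bcva_threshold_decimal,
            "bcva_threshold_logmar": self.bcva_threshold_logmar,
            "alpha": self.alpha,
            "r2_threshold": self.r2_threshold,
            "k_folds": self.k_folds,
            "n_repeats": self.n_repeats,
            "c_grid": list(self.c_grid),
            "tuning_objective": self.tuning_objective,
            "alignment_rule": self.alignment_rule,
            "ci_method": self.ci_method,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls(**{**data, "c_grid": tuple(data.get("c_grid", DEFAULT_C_GRID))})
        cfg.validate()
        return cfg


# --------------------------------------------------------------------------
# Group assignment and acuity conversion
# --------------------------------------------------------------------------


def logmar_from_decimal(decimal: float) -> float:
    if decimal <= 0:
        raise ValueError("decimal acuity must be positive")
    return -math.log10(decimal)


def decimal_from_logmar(logmar: float) -> float:
    return 10.0 ** (-logmar)


def assign_group(bcva_decimal: float, threshold_decimal: float = 0.7) -> str:
    """Prognosis group from the 6-month decimal BCVA: >= 0.7 -> A, < 0.7 -> B."""
    if bcva_decimal <= 0:
        raise ValueError("decimal acuity must be positive")
    return "A" if bcva_decimal >= threshold_decimal else "B"


# --------------------------------------------------------------------------
# Standardisation and fitting
# --------------------------------------------------------------------------


class ZeroVarianceError(ValueError):
    """A training feature has zero variance and cannot be z-scored."""


def standardize(train: np.ndarray, apply_to: np.ndarray | None = None):
    """Z-score with training-set mean and sample (n-1) SD.

    Returns ``(z, means, sds)``; ``apply_to`` (default: the training data
    itself) is transformed with the *training* parameters only.
    """
    train = np.asarray(train, dtype=float)
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ZeroVarianceError("zero-variance feature in training data")
    target = train if apply_to is None else np.asarray(apply_to, dtype=float)
    return (target - means) / sds, means, sds


@dataclass
class ModelBundle:
    """A fitted fold model: standardisation parameters, standardized
    coefficients, the regularisation constant and the aligned threshold."""

    feature_names: tuple[str, ...]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    coefficients: dict[str, float]
    intercept: float
    c_value: float
    threshold: float = 0.5

    def decision_scores(self, X_raw: np.ndarray) -> np.ndarray:
        """P(positive class) for raw (unstandardised) feature rows."""
        X = (np.asarray(X_raw, dtype=float) - self.feature_means) / self.feature_sds
        coef = np.array([self.coefficients[f] for f in self.feature_names])
        logits = self.intercept + X @ coef
        return 1.0 / (1.0 + np.exp(-logits))

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "c_value": self.c_value,
            "threshold": self.threshold,
        }


class SingleClassError(ValueError):
    """Training labels contain a single class."""


def fit_logistic(
    X: np.ndarray, y: np.ndarray, c_value: float,
    feature_names: tuple[str, ...] | None = None,
    means: np.ndarray | None = None, sds: np.ndarray | None = None,
) -> ModelBundle:
    """Maximise the L2-penalised binomial log-likelihood on standardized X.

    The objective is sum_i log-likelihood - (1 / (2 c)) ||w||^2 with the
    intercept unpenalised (the scikit-learn convention with C = c).  ``X``
    must already be z-scored; pass ``means``/``sds`` to embed the
    standardisation parameters in the returned bundle.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if len(np.unique(y)) < 2:
        raise SingleClassError("both classes must be present in y")
    clf = LogisticRegression(C=c_value, solver="lbfgs", max_iter=10_000, tol=1e-8)
    clf.fit(X, y.astype(int))
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    if means is None:
        means = np.zeros(X.shape[1])
    if sds is None:
        sds = np.ones(X.shape[1])
    coefficients = dict(zip(feature_names, clf.coef_[0].tolist()))
    return ModelBundle(
        feature_names=tuple(feature_names),
        feature_means=np.asarray(means, dtype=float),
        feature_sds=np.asarray(sds, dtype=float),
        coefficients=coefficients,
        intercept=float(clf.intercept_[0]),
        c_value=float(c_value),
    )


def penalized_log_likelihood(X: np.ndarray, y: np.ndarray, intercept: float,
                             coef: np.ndarray, c_value: float) -> float:
    """The training objective; exposed for verification against oracles."""
    logits = intercept + X @ np.asarray(coef, dtype=float)
    y = np.asarray(y, dtype=float)
    ll = float(np.sum(y * logits - np.logaddexp(0.0, logits)))
    return ll - float(np.sum(np.square(coef))) / (2.0 * c_value)


# --------------------------------------------------------------------------
# Hyperparameter fixing by frequency
# --------------------------------------------------------------------------


def tune_hyperparameter(
    X: np.ndarray, y: np.ndarray, config: PipelineConfig
) -> tuple[float, dict[float, int]]:
    """Fix the regularisation constant by its modal frequency over CV pre-tests.

    For each of ``n_repeats`` seeded repetitions, run stratified k-fold CV for
    every constant in the grid, score the pooled out-of-fold predictions by
    the tuning objective, and record the per-repeat winner (objective ties go
    to the stronger penalty, i.e. the smaller constant).  Returns the modal
    constant (mode ties likewise toward the smaller constant) and the full
    frequency histogram.
    """
    from . import evalcv  # local import to avoid a module cycle

    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    grid = sorted(config.c_grid)
    ss = np.random.SeedSequence([config.seed, 0x7E57])
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_repeats)]
    wins: Counter = Counter()
    for rep_seed in rep_seeds:
        folds = evalcv.stratified_kfold_indices(y, k=config.k_folds, seed=rep_seed)
        best_c, best_obj = None, -np.inf
        for c in grid:
            scores = np.empty(len(y))
            preds = np.empty(len(y), dtype=bool)
            ok = True
            for f in range(config.k_folds):
                test = folds == f
                train = ~test
                try:
                    z_train, mu, sd = standardize(X[train])
                except ZeroVarianceError:
                    ok = False
                    break
                bundle = fit_logistic(z_train, y[train], c, means=mu, sds=sd)
                scores[test] = bundle.decision_scores(X[test])
                if config.tuning_objective in ("f1", "accuracy"):
                    thr = align_threshold(bundle.decision_scores(X[train]), y[train],
                                          rule=config.alignment_rule)
                    preds[test] = scores[test] >= thr
            if not ok:
                continue
            if config.tuning_objective == "auc":
                obj = evalcv.rank_auc(y, scores)
            else:
                m = evalcv.confusion_metrics(y, preds)
                obj = m["f_measure"] if config.tuning_objective == "f1" else m["accuracy"]
            if obj > best_obj + 1e-12:
                best_c, best_obj = c, obj
        if best_c is not None:
            wins[best_c] += 1
    if not wins:
        raise RuntimeError("hyperparameter tuning produced no valid repetition")
    top = max(wins.values())
    c_star = min(c for c, k in wins.items() if k == top)
    histogram = {c: wins.get(c, 0) for c in grid}
    logger.info("hyperparameter frequencies over %d pre-tests: %s -> fixed c = %g",
                config.n_repeats, histogram, c_star)
    return c_star, histogram


# --------------------------------------------------------------------------
# Threshold alignment
# --------------------------------------------------------------------------


def align_threshold(scores: np.ndarray, labels: np.ndarray, rule: str = "precision") -> float:
    """Choose a decision threshold with a conservative operating point.

    Candidate thresholds are the midpoints of the sorted unique scores plus
    sentinels below the minimum (everything positive) and above the maximum
    (nothing positive; precision is defined as 1 there, recall 0).  Among the
    candidates satisfying the rule (``precision``: precision >= recall;
    ``accuracy``: accuracy >= recall) the threshold maximising F-measure is
    returned, ties resolved toward the higher threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise SingleClassError("threshold alignment needs both classes")
    uniq = np.unique(scores)
    cands = [uniq[0] - 0.5 * max(uniq[0], 1e-6)]
    cands.extend(((uniq[:-1] + uniq[1:]) / 2.0).tolist())
    cands.append(uniq[-1] + 0.5 * (1.0 - uniq[-1]) + 1e-9)
    best_t, best_f = None, -1.0
    n_pos = labels.sum()
    for t in cands:
        pred = scores >= t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        recall = tp / n_pos
        accuracy = float((pred == labels).mean())
        gate = precision if rule == "precision" else accuracy
        if gate < recall:
            continue
        f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        if f > best_f + 1e-12 or (abs(f - best_f) <= 1e-12 and t > best_t):
            best_t, best_f = t, f
    return float(best_t)


# --------------------------------------------------------------------------
# Coefficient reporting
# --------------------------------------------------------------------------


def collect_coefficients(bundles, ci_method: str = "t") -> dict[str, dict]:
    """Per-feature distribution of standardized coefficients over fold models.

    Reports mean, sample SD, 95% CI for the mean, and box-and-whisker
    statistics with 1.5 x IQR whiskers (whisker ends at the most extreme
    value inside the limits; values beyond are listed as outliers).
    """
    bundles = list(bundles)
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles")
    names = bundles[0].feature_names
    for b in bundles:
        if b.feature_names != names:
            raise ValueError("bundles have inconsistent feature sets")
    report: dict[str, dict] = {}
    n = len(bundles)
    for f in names:
        vals = np.array([b.coefficients[f] for b in bundles])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if ci_method == "t":
            crit = float(stats.t.ppf(0.975, n - 1))
        else:
            crit = float(stats.norm.ppf(0.975))
        half = crit * sd / math.sqrt(n)
        q1, q2, q3 = (float(q) for q in np.percentile(vals, [25, 50, 75]))
        iqr = q3 - q1
        lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_lim) & (vals <= hi_lim)]
        report[f] = {
            "mean": mean,
            "sd": sd,
            "ci": (mean - half, mean + half),
            "median": q2,
            "q1": q1,
            "q3": q3,
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
            "outliers": vals[(vals < lo_lim) | (vals > hi_lim)].tolist(),
        }
    return report
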