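"""Explanatory-variable selection: filter tests plus multicollinearity pruning.

The selection is a pure filter method.  Each of the 41 features is compared
between the good- and poor-prognosis groups — two-sample Kolmogorov–Smirnov
for continuous features, Fisher's exact test (Freeman–Halton extension for
r x c tables) for categorical ones — and features with p < alpha become
candidates; no multiplicity correction is applied.  Candidates are then
pruned for multicollinearity: each candidate is regressed (OLS) on all the
other remaining candidates, and while any auxiliary R^2 exceeds the threshold
(0.9, i.e. VIF > 10) the worst offender is dropped and the regressions are
repeated.  The full per-iteration trace is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .octfeat import (
    CATEGORICAL_LEVELS,
    FEATURE_NAMES,
    LABEL_COLUMN,
    canonical_order,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "ks_test",
    "fisher_test",
    "wilcoxon_signed_rank",
    "significance_filter",
    "vif_eliminate",
    "vif_from_r2",
    "select_features",
]


# --------------------------------------------------------------------------
# Two-group tests
# --------------------------------------------------------------------------


def ks_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test.

    The exact null distribution is used when n_a * n_b <= 1e4 (the regime of
    small clinical cohorts), the asymptotic one otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _log_table_prob(table: np.ndarray) -> float:
    """log P(table | margins) under the multivariate hypergeometric null."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def fill(i: int, remaining_cols: np.ndarray, acc: list):
        if i == r - 1:
            if (remaining_cols >= 0).all():
                yield np.array(acc + [remaining_cols])
            return
        # enumerate row i subject to its row sum and the remaining column sums
        def row_cells(j: int, left: int, cells: list):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield cells + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from row_cells(j + 1, left - v, cells + [v])

        for row in row_cells(0, int(rows[i]), []):
            yield from fill(i + 1, remaining_cols - np.array(row), acc + [row])

    yield from fill(0, cols.astype(int).copy(), [])


def fisher_test(table, mc_draws: int = 100_000, mc_seed: int = 0) -> float:
    """Two-sided Fisher exact p for an r x c contingency table.

    2x2 tables use the hypergeometric tail sum directly; larger tables use
    the Freeman–Halton extension (exact enumeration of all tables with the
    observed margins for total n <= 60, seeded permutation Monte Carlo with
    ``mc_draws`` resamples otherwise).  A degenerate margin (an all-zero row
    or column) carries no information and returns p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("contingency table must hold nonnegative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        logger.warning("degenerate margin in contingency table; returning p = 1")
        return 1.0
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    n = int(t.sum())
    obs = _log_table_prob(t)
    eps = 1e-9
    if n <= 60:
        p = 0.0
        for cand in _enumerate_tables(rows, cols):
            lp = _log_table_prob(cand)
            if lp <= obs + eps:
                p += np.exp(lp)
        return float(min(p, 1.0))
    # permutation Monte Carlo: shuffle the column assignment of records
    rng = np.random.default_rng(mc_seed)
    row_labels = np.repeat(np.arange(t.shape[0]), rows)
    col_labels = np.repeat(np.arange(t.shape[1]), cols)
    hits = 0
    for _ in range(mc_draws):
        perm = rng.permutation(col_labels)
        cand = np.zeros_like(t)
        np.add.at(cand, (row_labels, perm), 1)
        if _log_table_prob(cand) <= obs + eps:
            hits += 1
    return float((hits + 1) / (mc_draws + 1))


def wilcoxon_signed_rank(paired_before, paired_after) -> float:
    """Two-sided Wilcoxon signed-rank p for paired measurements.

    Zero differences are dropped; ties are mid-ranked.  If every difference
    is zero the test carries no information and p = 1.
    """
    before = np.asarray(paired_before, dtype=float)
    after = np.asarray(paired_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if before.size < 5:
        raise ValueError("need at least 5 pairs")
    diff = after - before
    if np.all(diff == 0):
        return 1.0
    res = stats.wilcoxon(before, after, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


# --------------------------------------------------------------------------
# Candidate filtering
# --------------------------------------------------------------------------


def significance_filter(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], dict[str, float]]:
    """Per-feature two-group tests; returns (candidates with p < alpha, all p).

    Continuous features use the KS test, categorical features Fisher's exact
    test on the level x group contingency table.  Constant features get p = 1
    (logged).  No multiple-testing correction is applied.
    """
    if LABEL_COLUMN not in table:
        raise ValueError(f"table lacks the {LABEL_COLUMN!r} column")
    groups = [g for _, g in table.groupby(LABEL_COLUMN, sort=True)]
    if len(groups) != 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need two groups with at least 2 records each")
    ga, gb = groups
    p_values: dict[str, float] = {}
    for name in FEATURE_NAMES:
        if name not in table:
            continue
        if table[name].nunique() <= 1:
            logger.info("feature %r is constant; p set to 1", name)
            p_values[name] = 1.0
            continue
        if name in CATEGORICAL_LEVELS:
            crosstab = pd.crosstab(table[name], table[LABEL_COLUMN])
            p_values[name] = fisher_test(crosstab.to_numpy())
        else:
            _, p_values[name] = ks_test(ga[name].to_numpy(), gb[name].to_numpy())
    candidates = [f for f in canonical_order(p_values) if p_values[f] < alpha]
    return candidates, p_values


# --------------------------------------------------------------------------
# Multicollinearity elimination
# --------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Outcome of the two-stage variable selection."""

    p_values: dict[str, float]
    candidates: list[str]
    elimination_trace: list[dict] = field(default_factory=list)
    final_variables: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "p_values": self.p_values,
            "candidates": self.candidates,
            "elimination_trace": self.elimination_trace,
            "final_variables": self.final_variables,
        }


def vif_from_r2(r2: float) -> float:
    """Variance inflation factor 1 / (1 - R^2); R^2 = 0.9 maps to VIF = 10."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("R^2 must lie in [0, 1)")
    return 1.0 / (1.0 - r2)


def encode_numeric(table: pd.DataFrame, features) -> pd.DataFrame:
    """Numeric view of selected features (categorical levels -> integer codes)."""
    out = {}
    for name in features:
        col = table[name]
        if name in CATEGORICAL_LEVELS:
            codes = {lvl: i for i, lvl in enumerate(CATEGORICAL_LEVELS[name])}
            out[name] = col.astype(str).map(codes).astype(float)
        else:
            out[name] = col.astype(float)
    return pd.DataFrame(out, index=table.index)


def _auxiliary_r2(X: np.ndarray, j: int) -> float:
    """R^2 of column j regressed on the remaining columns plus an intercept."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(np.clip(r2, 0.0, 1.0))


def vif_eliminate(
    table: pd.DataFrame, candidates: list[str], r2_threshold: float = 0.9,
    p_values: dict[str, float] | None = None,
) -> SelectionResult:
    """Iteratively drop the candidate with the largest auxiliary R^2 > threshold.

    One feature is dropped per iteration (exact ties broken by dropping the
    feature later in canonical order); the loop stops when every remaining
    auxiliary R^2 is <= the threshold.  A perfectly collinear candidate has
    R^2 = 1 and is dropped first.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates for multicollinearity pruning")
    if len(table) <= len(candidates):
        raise ValueError("need more records than candidates")
    remaining = canonical_order(candidates)
    rank = {n: i for i, n in enumerate(FEATURE_NAMES)}
    trace: list[dict] = []
    iteration = 0
    while len(remaining) >= 2:
        iteration += 1
        X = encode_numeric(table, remaining).to_numpy()
        r2 = {f: _auxiliary_r2(X, j) for j, f in enumerate(remaining)}
        worst = max(r2.values())
        if worst <= r2_threshold:
            trace.append({"iteration": iteration, "r2_scores": r2, "dropped": None})
            break
        tied = [f for f in remaining if r2[f] >= worst - 1e-12]
        dropped = max(tied, key=lambda f: rank[f])
        trace.append({"iteration": iteration, "r2_scores": r2, "dropped": dropped})
        logger.info("iteration %d: dropped %r (R^2 = %.3f, VIF = %.1f)",
                    iteration, dropped, r2[dropped], vif_from_r2(min(r2[dropped], 1 - 1e-12)))
        remaining = [f for f in remaining if f != dropped]
    else:
        trace.append({"iteration": iteration + 1, "r2_scores": {remaining[0]: 0.0},
                      "dropped": None})
    return SelectionResult(
        p_values=dict(p_values or {}),
        candidates=list(candidates),
        elimination_trace=trace,
        final_variables=remaining,
    )


def select_features(
    table: pd.DataFrame, alpha: float = 0.05, r2_threshold: float = 0.9
) -> SelectionResult:
    """Full selection: significance filter then VIF elimination.

    If no feature clears the significance filter (possible in small
    replicate cohorts), the single smallest-p feature is kept so the
    downstream model remains estimable; the fallback is logged.
    """
    candidates, p_values = significance_filter(table, alpha=alpha)
    if not candidates:
        fallback = min(p_values, key=lambda f: (p_values[f], FEATURE_NAMES.index(f)))
        logger.warning(
            "no feature significant at alpha=%.3g; falling back to smallest-p feature %r (p=%.3g)",
            alpha, fallback, p_values[fallback],
        )
        candidates = [fallback]
    if len(candidates) < 2:
        return SelectionResult(p_values=p_values, candidates=candidates,
                               elimination_trace=[], final_variables=list(candidates))
    return vif_eliminate(table, candidates, r2_threshold=r2_threshold, p_values=p_values)
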