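"""Accuracy metrics, permutation model comparison, effect sizes, FDR, ECE.

Four per-feature accuracy metrics summarise agreement between observed
values and predicted means: median absolute error, RMSE, Spearman's rho and
explained variance. Model comparisons use a median-based permutation test on
the pooled per-feature score vectors with Cliff's delta as effect size and
Benjamini-Hochberg FDR across comparisons. Calibration of the full
predictive distribution is scored by the expected calibration error (ECE):
the mean absolute gap between nominal and observed central-interval coverage
over confidence levels 0.05, 0.15, ..., 0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "median_ae",
    "rmse",
    "spearman_rho",
    "explained_variance",
    "metric_table",
    "cliffs_delta",
    "fdr_adjust",
    "PermutationResult",
    "permutation_median_test",
    "ECEResult",
    "expected_calibration_error",
    "DEFAULT_CONFIDENCE_LEVELS",
]

#: 0.05 to 0.95 in steps of 0.1 — ten central-interval confidence levels.
DEFAULT_CONFIDENCE_LEVELS = tuple(np.round(np.arange(0.05, 1.0, 0.1), 2))


def _check_pair(y: np.ndarray, mu: np.ndarray, min_len: int = 1):
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    if y.shape != mu.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} observations")
    return y, mu


def median_ae(y, mu) -> float:
    """Median of the absolute prediction errors; 0 for a perfect prediction."""
    y, mu = _check_pair(y, mu)
    return float(np.median(np.abs(y - mu)))


def rmse(y, mu) -> float:
    """Root mean squared prediction error."""
    y, mu = _check_pair(y, mu)
    return float(np.sqrt(np.mean(np.square(y - mu))))


def spearman_rho(y, mu) -> float:
    """Rank correlation (midranks for ties); NaN with a warning if degenerate."""
    y, mu = _check_pair(y, mu, min_len=2)
    if np.ptp(y) == 0 or np.ptp(mu) == 0:
        warnings.warn("constant vector: Spearman's rho undefined, returning NaN")
        return float("nan")
    return float(stats.spearmanr(y, mu).statistic)


def explained_variance(y, mu) -> float:
    """``1 - SS_res / SS_tot``; 1 is perfect, 0 matches the constant-mean rule."""
    y, mu = _check_pair(y, mu, min_len=2)
    ss_tot = float(np.sum(np.square(y - y.mean())))
    if ss_tot == 0:
        raise ValueError("zero-variance observations: explained variance undefined")
    return float(1.0 - np.sum(np.square(y - mu)) / ss_tot)


def metric_table(Y: np.ndarray, mu: np.ndarray, feature_names=None,
                 model: str = "model") -> pd.DataFrame:
    """All four metrics per feature for one model's predicted means."""
    Y = np.atleast_2d(Y)
    mu = np.atleast_2d(mu)
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(Y.shape[1])]
    rows = []
    for j, name in enumerate(feature_names):
        rows.append(
            {
                "model": model,
                "feature": name,
                "median_ae": median_ae(Y[:, j], mu[:, j]),
                "rmse": rmse(Y[:, j], mu[:, j]),
                "spearman_rho": spearman_rho(Y[:, j], mu[:, j]),
                "explained_variance": explained_variance(Y[:, j], mu[:, j]),
            }
        )
    return pd.DataFrame(rows)


def cliffs_delta(a, b) -> float:
    """``(#{a > b} - #{a < b}) / (|a| |b|)`` over all pairs, in [-1, 1].

    Computed by sorting ``b`` (O((n+m) log m)) rather than forming all pairs.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    bs = np.sort(b)
    greater = np.searchsorted(bs, a, side="left")  # # b < a_i
    less = b.size - np.searchsorted(bs, a, side="right")  # # b > a_i
    return float((greater.sum() - less.sum()) / (a.size * b.size))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


@dataclass
class PermutationResult:
    """Outcome of one median-based permutation comparison."""

    label: str
    observed_median_diff: float
    cliffs_delta: float
    n_permutations: int
    p_value: float
    p_fdr: float | None = None


def permutation_median_test(
    scores_a,
    scores_b,
    n_perm: int = 10_000,
    seed: int = 0,
    label: str = "A vs B",
) -> PermutationResult:
    """Two-sample median-difference permutation test on pooled scores.

    The observed statistic is ``median(a) - median(b)``. The null is built by
    pooling both score vectors and re-partitioning them ``n_perm`` times into
    groups of the original sizes; the empirical p-value is the proportion of
    shuffled |differences| >= the observed |difference|, floored at
    ``1/n_perm`` so p is never exactly 0.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both score vectors must be non-empty")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    observed = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    # one permuted copy of the pool per row, split at |a|
    perm = np.tile(pooled, (n_perm, 1))
    rng.permuted(perm, axis=1, out=perm)
    null = np.median(perm[:, : a.size], axis=1) - np.median(perm[:, a.size :], axis=1)
    p = float(np.mean(np.abs(null) >= abs(observed)))
    p = max(p, 1.0 / n_perm)
    return PermutationResult(
        label=label,
        observed_median_diff=observed,
        cliffs_delta=cliffs_delta(a, b),
        n_permutations=n_perm,
        p_value=p,
    )


@dataclass
class ECEResult:
    """Calibration summary for one feature."""

    ece: float
    levels: np.ndarray
    coverage: np.ndarray

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"confidence_level": self.levels,
                             "observed_coverage": self.coverage})


def expected_calibration_error(
    mu, sd, y, levels=DEFAULT_CONFIDENCE_LEVELS
) -> ECEResult:
    """ECE of Gaussian predictive intervals for one feature.

    For each confidence level alpha the central interval is
    ``mu ± z_{(1+alpha)/2} sd``; coverage is the fraction of observations
    inside it, and the ECE is the mean absolute coverage gap over levels.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("need at least one confidence level")
    mu = np.asarray(mu, dtype=float).ravel()
    sd = np.asarray(sd, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.any(sd <= 0):
        raise ValueError("predictive SD must be positive")
    zq = stats.norm.ppf((1.0 + levels) / 2.0)
    inside = np.abs(y - mu)[:, None] <= zq[None, :] * sd[:, None]
    coverage = inside.mean(axis=0)
    return ECEResult(
        ece=float(np.mean(np.abs(coverage - levels))),
        levels=levels,
        coverage=coverage,
    )
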