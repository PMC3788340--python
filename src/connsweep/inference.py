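"""Permutation-based group inference on AUC summaries.

The between-group statistic is the difference of group means.  Its null
distribution is built by re-splitting the pooled subjects into groups of the
original sizes: uniformly at random (Monte Carlo, with the add-one p-value
estimator, so p is never 0) or exhaustively whenever the total number of
splits does not exceed the requested permutation count (there the observed
split is itself enumerated, so the plain count/total p is already positive).

Regions are flagged as group-different when at least one of their three
nodal metrics (degree, efficiency, betweenness) reaches the permutation
threshold.  Note this union rule inflates the per-region type-I error above
the per-metric alpha; the per-metric p-values are always reported so callers
can apply stricter control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "permutation_test",
    "permutation_test_table",
    "flag_changed_regions",
    "correlate_training",
]


@dataclass
class PermutationResult:
    metric_name: str
    region: str  # "global" or a region identifier
    observed_diff: float
    null_diffs: np.ndarray
    p_two_sided: float
    exhaustive: bool = False


def _split_matrix(n_total: int, n_a: int, n_perm: int, rng: np.random.Generator):
    """(n_perm x n_total) +1/n_a, -1/n_b contrast rows; exhaustive if small."""
    n_b = n_total - n_a
    n_splits = math.comb(n_total, n_a)
    exhaustive = n_splits <= n_perm
    if exhaustive:
        m = np.full((n_splits, n_total), -1.0 / n_b)
        for row, idx in enumerate(combinations(range(n_total), n_a)):
            m[row, list(idx)] = 1.0 / n_a
    else:
        m = np.full((n_perm, n_total), -1.0 / n_b)
        order = np.argsort(rng.random((n_perm, n_total)), axis=1)
        rows = np.repeat(np.arange(n_perm), n_a)
        m[rows, order[:, :n_a].ravel()] = 1.0 / n_a
    return m, exhaustive


def permutation_test(
    auc_a: Sequence[float],
    auc_b: Sequence[float],
    n_perm: int = 5000,
    seed: int = 0,
    metric_name: str = "",
    region: str = "global",
) -> PermutationResult:
    """Two-sided permutation test on the difference of group means."""
    a = np.asarray(auc_a, float)
    b = np.asarray(auc_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two subjects per group")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    observed = float(a.mean() - b.mean())
    if np.ptp(pooled) == 0.0:
        return PermutationResult(metric_name, region, observed, np.zeros(0), 1.0)
    rng = np.random.default_rng(seed)
    m, exhaustive = _split_matrix(pooled.size, a.size, n_perm, rng)
    null = m @ pooled
    n_extreme = int((np.abs(null) >= abs(observed) - 1e-12).sum())
    if exhaustive:
        p = n_extreme / null.size
    else:
        p = (n_extreme + 1) / (null.size + 1)
    return PermutationResult(metric_name, region, observed, null, float(p), exhaustive)


def permutation_test_table(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    metric_name: str = "",
) -> pd.DataFrame:
    """Permutation tests across many columns sharing one set of splits.

    ``values_a``/``values_b`` are subjects x regions tables with identical
    columns.  Returns a DataFrame indexed by column with observed mean
    difference (A - B), two-sided p, and direction.
    """
    if list(values_a.columns) != list(values_b.columns):
        raise ValueError("column sets differ between groups")
    xa, xb = values_a.to_numpy(float), values_b.to_numpy(float)
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("need at least two subjects per group")
    pooled = np.vstack([xa, xb])
    observed = xa.mean(axis=0) - xb.mean(axis=0)
    rng = np.random.default_rng(seed)
    m, exhaustive = _split_matrix(pooled.shape[0], xa.shape[0], n_perm, rng)
    null = m @ pooled  # (n_splits x n_regions)
    n_extreme = (np.abs(null) >= np.abs(observed)[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        p = n_extreme / null.shape[0]
    else:
        p = (n_extreme + 1) / (null.shape[0] + 1)
    degenerate = np.ptp(pooled, axis=0) == 0.0
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "metric": metric_name,
            "observed_diff": observed,
            "p": p,
            "direction": np.where(observed > 0, "A>B", np.where(observed < 0, "A<B", "=")),
        },
        index=values_a.columns,
    )


def flag_changed_regions(
    nodal_results: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Flag regions with p < alpha in at least one nodal metric.

    ``nodal_results`` maps metric name -> per-region table from
    ``permutation_test_table``.  Returns the flagged regions sorted by region
    index, with per-metric p-values and directions.
    """
    metrics = list(nodal_results)
    first = nodal_results[metrics[0]]
    out = pd.DataFrame(index=first.index)
    for m in metrics:
        tbl = nodal_results[m]
        if not tbl.index.equals(first.index):
            raise ValueError("nodal result tables have mismatched regions")
        out[f"p_{m}"] = tbl["p"].to_numpy()
        out[f"direction_{m}"] = tbl["direction"].to_numpy()
        out[f"diff_{m}"] = tbl["observed_diff"].to_numpy()
    p_cols = [f"p_{m}" for m in metrics]
    out["min_p"] = out[p_cols].min(axis=1)
    flagged = out[out["min_p"] < alpha].copy()
    return flagged


def correlate_training(
    auc_by_region: pd.DataFrame,
    training_years: Sequence[float],
    alpha_family: float = 0.05,
    n_comparisons: Optional[int] = None,
) -> pd.DataFrame:
    """Pearson correlation of per-region AUC with training duration.

    Bonferroni significance divides ``alpha_family`` by ``n_comparisons``
    (default: the number of regions, 110 at the standard parcellation).
    Regions passing the uncorrected 0.05 level are reported as well.
    Zero-variance inputs yield NaN r with a logged warning.
    """
    y = np.asarray(training_years, float)
    x = auc_by_region.to_numpy(float)
    if y.size != x.shape[0]:
        raise ValueError("training_years length does not match subject count")
    if y.size < 3:
        raise ValueError("need at least three subjects with training values")
    if n_comparisons is None:
        n_comparisons = x.shape[1]
    bonf = alpha_family / n_comparisons

    r = np.full(x.shape[1], np.nan)
    p = np.full(x.shape[1], np.nan)
    if y.std() == 0:
        logger.warning("correlate_training: training durations are constant; r undefined")
    else:
        for j in range(x.shape[1]):
            if x[:, j].std() == 0:
                logger.warning(
                    "correlate_training: zero-variance AUC in region %s", auc_by_region.columns[j]
                )
                continue
            r[j], p[j] = stats.pearsonr(x[:, j], y)
    return pd.DataFrame(
        {
            "r": r,
            "p": p,
            "significant_bonferroni": p < bonf,
            "significant_uncorrected": p < alpha_family,
        },
        index=auc_by_region.columns,
    )
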