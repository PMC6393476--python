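"""Small shared statistical helpers used across modules."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

#: sample-size ceiling below which exact rank-sum enumeration is used
EXACT_RANKSUM_MAX = 25


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the pooled sample has at most
    ``EXACT_RANKSUM_MAX`` observations and no ties, normal approximation
    with tie correction otherwise.  Returns ``(U_statistic, p)``; the
    degenerate all-tied case is assigned p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return np.nan, np.nan
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    n = pooled.size
    has_ties = np.unique(pooled).size < n
    method = "exact" if (n <= EXACT_RANKSUM_MAX and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def log_normalize(values: sp.spmatrix | np.ndarray, scale: float = 1e4) -> np.ndarray:
    """ln(1 + scale * count / library_size), genes x cells, dense output."""
    dense = np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)
    totals = dense.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("log_normalize requires positive column totals")
    return np.log1p(dense / totals * scale)


def normalized_counts(values: sp.spmatrix | np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Library-size-normalized (not logged) expression, genes x cells."""
    dense = np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)
    totals = dense.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("normalization requires positive column totals")
    return dense / totals * scale


def ranksum_matrix(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p values, group vs rest.

    ``values`` is genes x cells; ``in_group`` a boolean cell mask.  Uses the
    normal approximation with tie correction (vectorized over genes), with
    all-tied rows assigned p = 1.
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    res = st.mannwhitneyu(
        values[:, in_group], values[:, ~in_group], alternative="two-sided",
        method="asymptotic", axis=1,
    )
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.all(values == values[:, [0]], axis=1)
    p[constant] = 1.0
    return np.minimum(p, 1.0)
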