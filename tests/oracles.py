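"""Independent brute-force oracles used to validate the statistical core.

Everything here is deliberately naive — enumeration and direct arithmetic
only — and shares no code path with the package implementations.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import scipy.stats as st


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = st.rankdata(pooled)
    observed = ranks[:n].sum()
    total = comb(n + m, n)
    mean = n * (n + m + 1) / 2.0
    count = 0
    for idx in combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        if abs(w - mean) >= abs(observed - mean) - 1e-9:
            count += 1
    return count / total


def hypergeom_tail_p(overlap: int, n_query: int, n_ref: int, n_universe: int) -> float:
    """One-sided (greater) Fisher p by summing hypergeometric point masses."""
    upper = min(n_query, n_ref)
    total = 0.0
    for k in range(overlap, upper + 1):
        total += (
            comb(n_ref, k) * comb(n_universe - n_ref, n_query - k) / comb(n_universe, n_query)
        )
    return min(total, 1.0)


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic as the maximum ECDF gap over all data points."""
    grid = np.concatenate([x, y])
    d = 0.0
    for value in grid:
        fx = np.mean(x <= value)
        fy = np.mean(y <= value)
        d = max(d, abs(fx - fy))
    return d


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """BH adjusted p values by the textbook step-up recursion."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    previous = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(previous, p[i] * m / rank)
        adjusted[i] = value
        previous = value
    return adjusted


def mwu_score(fc: np.ndarray, member: np.ndarray) -> float:
    """2U/(n1 n2) - 1 by direct pair counting (ties count half)."""
    inside = fc[member]
    outside = fc[~member]
    wins = 0.0
    for a in inside:
        for b in outside:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return 2.0 * wins / (len(inside) * len(outside)) - 1.0


def twoway_anova_interaction_F(values: np.ndarray) -> float:
    """Balanced two-way ANOVA interaction F from the sums-of-squares identity.

    ``values`` has shape (levels_a, levels_b, replicates).
    """
    a, b, r = values.shape
    grand = values.mean()
    mean_a = values.mean(axis=(1, 2))
    mean_b = values.mean(axis=(0, 2))
    mean_ab = values.mean(axis=2)
    ss_inter = r * np.sum(
        (mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_err = np.sum((values - mean_ab[:, :, None]) ** 2)
    df_inter = (a - 1) * (b - 1)
    df_err = a * b * (r - 1)
    return (ss_inter / df_inter) / (ss_err / df_err)
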