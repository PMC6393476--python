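"""Detergent-solubility profiling (QDSP) statistics and proteome-wide
differential abundance.

QDSP extracts proteins from tissue with detergents of increasing
stringency into four fractions (FR1, FR2, FR3, INSOL); insolubility is a
proxy for incorporation into higher-order extracellular-matrix structures.
The per-protein analysis normalizes each age group's log2 intensities to
mean zero (which removes the age main effect by construction) and tests
the age x fraction interaction of a two-way fixed-effects ANOVA — a
significant interaction means the solubility *profile* changed with age.
Whole-tissue differential abundance uses a pooled-variance t-test, and a
rank-based two-dimensional annotation enrichment relates transcriptome and
proteome fold changes at the gene-category level.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats as st

from ._stats import bh_adjust
from .sim import FRACTIONS

QDSP_COLUMNS = ("protein_id", "age", "replicate", "fraction", "log2_intensity")


def _validate_qdsp(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(QDSP_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"QDSP table lacks columns: {sorted(missing)}")
    bad = set(table["fraction"].unique()) - set(FRACTIONS)
    if bad:
        raise ValueError(f"unknown solubility fraction labels: {sorted(bad)} (expected {FRACTIONS})")
    dup = table.duplicated(subset=["protein_id", "age", "replicate", "fraction"])
    if dup.any():
        raise ValueError("(age, replicate, fraction) must be unique per protein")
    return table


def qdsp_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Center each protein's log2 intensities to mean zero within each age.

    Proteins observed in only one age group are excluded and reported.
    After the operation both per-protein age-group means are exactly zero.
    """
    table = _validate_qdsp(table).dropna(subset=["log2_intensity"]).copy()
    counts = table.groupby(["protein_id", "age"]).size().unstack(fill_value=0)
    for age in ("young", "old"):
        if age not in counts.columns:
            counts[age] = 0
    excluded = sorted(counts.index[(counts["young"] < 2) | (counts["old"] < 2)].astype(str))
    table = table[~table["protein_id"].isin(excluded)]
    means = table.groupby(["protein_id", "age"])["log2_intensity"].transform("mean")
    table["log2_intensity"] = table["log2_intensity"] - means
    return table.reset_index(drop=True), excluded


def _twoway_anova_interaction(sub: pd.DataFrame) -> tuple[float, float]:
    """Interaction F and p of age x fraction (type II sums of squares)."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.ols("log2_intensity ~ C(age) * C(fraction)", data=sub).fit()
        table = anova_lm(model, typ=2)
    row = table.loc["C(age):C(fraction)"]
    return float(row["F"]), float(row["PR(>F)"])


def solubility_anova(
    normalized: pd.DataFrame,
    fdr: float = 0.20,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Per-protein two-way ANOVA of age x solubility fraction.

    Only the interaction term is of interest: it flags proteins whose
    solubility profile changes with age.  Proteins with any design cell
    below ``min_replicates`` observations are skipped with a reason.  BH
    adjustment runs across tested proteins; ``significant`` means
    p_adj < ``fdr``.
    """
    normalized = _validate_qdsp(normalized).dropna(subset=["log2_intensity"])
    rows = []
    for protein, sub in normalized.groupby("protein_id"):
        cell_counts = sub.groupby(["age", "fraction"]).size()
        full = len(cell_counts) == 2 * len(FRACTIONS) and cell_counts.min() >= min_replicates
        if not full:
            rows.append((str(protein), np.nan, np.nan, "incomplete_design"))
            continue
        F, p = _twoway_anova_interaction(sub)
        rows.append((str(protein), F, p, pd.NA))
    out = pd.DataFrame(rows, columns=["protein_id", "interaction_F", "p", "skip_reason"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < fdr
    return out


def abundance_ttest(
    tissue_log2: pd.DataFrame,
    age: pd.Series | Mapping[str, str],
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Pooled-variance two-sided t-test of old vs young per protein.

    ``tissue_log2`` is proteins x samples.  Exactly equal groups get p = 1;
    zero pooled variance with a nonzero difference leaves p missing and
    flags the protein.
    """
    age = pd.Series(age).reindex(tissue_log2.columns)
    if age.isna().any():
        raise ValueError("every sample needs an age label")
    old = tissue_log2.loc[:, (age == "old").to_numpy()].to_numpy(dtype=float)
    young = tissue_log2.loc[:, (age == "young").to_numpy()].to_numpy(dtype=float)
    if old.shape[1] < 2 or young.shape[1] < 2:
        raise ValueError("need at least two samples per age")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = st.ttest_ind(old, young, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    lfc = old.mean(axis=1) - young.mean(axis=1)
    pooled_var = old.var(axis=1, ddof=1) + young.var(axis=1, ddof=1)
    degenerate = pooled_var == 0
    p[degenerate & (lfc == 0)] = 1.0
    flagged = degenerate & (lfc != 0)
    p[flagged] = np.nan
    out = pd.DataFrame(
        {
            "protein_id": tissue_log2.index,
            "log2fc": lfc,
            "t": np.asarray(res.statistic, dtype=float),
            "p": p,
            "zero_variance": flagged,
        }
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < fdr
    return out.set_index("protein_id")


def _dimension_score(fc: np.ndarray, member: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U-based enrichment score s = 2U/(n1 n2) - 1 and its p."""
    n1 = int(member.sum())
    n2 = int((~member).sum())
    res = st.mannwhitneyu(fc[member], fc[~member], alternative="two-sided", method="asymptotic")
    s = 2.0 * float(res.statistic) / (n1 * n2) - 1.0
    return s, float(res.pvalue)


def annotation_enrichment_2d(
    fc_x: pd.Series,
    fc_y: pd.Series,
    gene_sets: Mapping[str, Iterable[str]],
    min_size: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Rank-based 2D annotation enrichment over two fold-change dimensions.

    Per category, each dimension gets a normalized Mann-Whitney score
    s in [-1, 1] (positive: members rank high) with its rank-sum p; the
    category p is the conservative max of the two and is BH-adjusted
    across categories.
    """
    universe = fc_x.dropna().index.intersection(fc_y.dropna().index)
    x = fc_x.loc[universe].to_numpy(dtype=float)
    y = fc_y.loc[universe].to_numpy(dtype=float)
    index = pd.Index(universe)
    rows = []
    for name, genes in gene_sets.items():
        member = index.isin(set(genes))
        n1 = int(member.sum())
        if n1 < min_size or n1 == len(index):
            continue
        s_x, p_x = _dimension_score(x, member)
        s_y, p_y = _dimension_score(y, member)
        rows.append((str(name), n1, s_x, s_y, p_x, p_y, max(p_x, p_y)))
    out = pd.DataFrame(
        rows, columns=["category", "n_members", "s_x", "s_y", "p_x", "p_y", "p"]
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < fdr
    return out
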