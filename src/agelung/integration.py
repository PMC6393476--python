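"""Pseudobulk construction, NB differential expression, cross-modality
merging, signature deconvolution, PCA projection, concordance, and
upstream-regulator scoring.

Pseudobulk ("in silico bulk") samples are per-mouse sums of single-cell UMI
counts.  Differential expression between ages uses a per-gene negative
binomial GLM (log link, median-of-ratios size factors as offsets, per-gene
dispersion by maximum likelihood) with a Wald test on the age coefficient.
The three modalities (pseudobulk, bulk, proteome) are merged on shared
genes, jointly quantile normalized, and embedded by PCA; cell-type marker
signatures are scored against bulk fold changes with a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.decomposition import PCA

from ._stats import bh_adjust
from .containers import CountMatrix

KS_P_FLOOR = 1e-50
ACTIVATION_Z = 2.0
ACTIVATION_NEGLOG10_P = 7.0


def pseudobulk(matrix: CountMatrix, mouse_ids: Iterable[str]) -> pd.DataFrame:
    """Sum UMI counts across all cells of each mouse (genes x mice)."""
    mouse_ids = np.asarray(list(mouse_ids), dtype=object)
    if mouse_ids.size != matrix.n_barcodes:
        raise ValueError("mouse_ids must align with barcodes")
    dense = np.asarray(matrix.values.todense(), dtype=np.int64)
    out = {}
    for mouse in pd.unique(mouse_ids):
        out[str(mouse)] = dense[:, mouse_ids == mouse].sum(axis=1)
    return pd.DataFrame(out, index=matrix.gene_ids)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors from the geometric-mean reference sample."""
    values = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(values).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has all-positive counts; size factors undefined")
    ratios = np.log(values[usable]) - log_geo[usable, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    from scipy.special import gammaln

    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def _fit_gene_nb(y: np.ndarray, exog: np.ndarray, offset: np.ndarray, alpha_floor: float):
    from scipy.optimize import minimize_scalar

    def fit_glm(alpha: float):
        fam = sm.families.NegativeBinomial(alpha=max(alpha, alpha_floor))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(y, exog, family=fam, offset=offset).fit()

    alpha = 0.1
    fit = fit_glm(alpha)
    for _ in range(2):
        mu = fit.mu

        def nll(log_alpha: float) -> float:
            return -_nb_loglik(y, mu, float(np.exp(log_alpha)))

        res = minimize_scalar(nll, bounds=(np.log(alpha_floor), np.log(1e3)), method="bounded")
        alpha = float(np.exp(res.x))
        fit = fit_glm(alpha)
    return fit, alpha


def nb_differential(
    counts: pd.DataFrame,
    age: pd.Series | Mapping[str, str],
    min_total: int = 10,
    alpha_floor: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB GLM differential expression, old vs young.

    Genes with total counts below ``min_total`` are filtered before
    testing.  Returns log2FC (old vs young), its standard error, the Wald
    statistic, p, and BH-adjusted p.
    """
    age = pd.Series(age).reindex(counts.columns)
    if age.isna().any():
        raise ValueError("every sample needs an age label")
    for group in ("young", "old"):
        if (age == group).sum() < 2:
            raise ValueError(f"need at least two {group} samples")
    keep = counts.sum(axis=1) >= min_total
    filtered = counts.loc[keep]
    sf = median_of_ratios_size_factors(filtered)
    offset = np.log(sf.to_numpy())
    is_old = (age == "old").to_numpy(dtype=float)
    exog = sm.add_constant(is_old)
    ln2 = np.log(2.0)
    rows = []
    for gene, y in filtered.iterrows():
        y = y.to_numpy(dtype=float)
        if np.all(y == y[0]) and np.all(y == 0):
            continue
        try:
            fit, alpha = _fit_gene_nb(y, exog, offset, alpha_floor)
            beta, se = float(fit.params[1]), float(fit.bse[1])
            stat = beta / se if se > 0 else np.nan
            p = 2.0 * st.norm.sf(abs(stat)) if np.isfinite(stat) else 1.0
            rows.append((gene, beta / ln2, se / ln2, stat, min(p, 1.0), alpha))
        except Exception:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["gene", "log2fc", "se", "stat", "p", "dispersion"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.set_index("gene")


def log_cpm(counts: pd.DataFrame, offset: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a +0.5 offset (limma-style)."""
    lib = counts.sum(axis=0)
    return np.log2((counts + offset).div(lib + 1.0, axis=1) * 1e6)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Joint quantile normalization across all columns.

    Every column receives the row means of the column-sorted matrix; tied
    values within a column get the average of the reference values at
    their tied rank positions.
    """
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    positions = np.arange(1, values.shape[0] + 1, dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = st.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def merge_modalities(
    pseudobulk_log: pd.DataFrame,
    bulk_log: pd.DataFrame,
    proteome_log: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Merge three log-scale matrices on shared genes, quantile normalize
    jointly, and run PCA on the samples.

    Returns (merged normalized matrix, sample scores with modality labels,
    explained variance ratios).
    """
    shared = pseudobulk_log.index.intersection(bulk_log.index).intersection(proteome_log.index)
    if len(shared) < 3:
        raise ValueError("fewer than three genes shared across modalities")
    parts = {
        "pseudobulk": pseudobulk_log.loc[shared],
        "bulk": bulk_log.loc[shared],
        "proteome": proteome_log.loc[shared],
    }
    merged = pd.concat(parts.values(), axis=1)
    modality = np.concatenate([[name] * p.shape[1] for name, p in parts.items()])
    normalized = quantile_normalize(merged)
    X = normalized.to_numpy().T
    k = min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=k, random_state=0)
    scores = pca.fit_transform(X - X.mean(axis=0))
    frame = pd.DataFrame(
        scores, index=normalized.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    frame["modality"] = modality
    return normalized, frame, pca.explained_variance_ratio_


def ks_signature_enrichment(
    fold_changes: pd.Series,
    marker_sets: Mapping[str, Iterable[str]],
    min_markers: int = 5,
) -> pd.DataFrame:
    """Two-sample KS enrichment of marker-gene fold changes per cell type.

    ``direction`` is the sign of the marker-vs-rest median difference; p
    values are clamped to [1e-50, 1].
    """
    fc = fold_changes.dropna()
    rows = []
    for ct, genes in marker_sets.items():
        members = fc.index.intersection(pd.Index(set(genes)))
        if len(members) < min_markers:
            warnings.warn(f"signature {ct!r} has {len(members)} scored markers (<{min_markers}); skipped")
            continue
        inside = fc.loc[members].to_numpy()
        outside = fc.drop(members).to_numpy()
        res = st.ks_2samp(inside, outside, alternative="two-sided")
        p = float(np.clip(res.pvalue, KS_P_FLOOR, 1.0))
        direction = int(np.sign(np.median(inside) - np.median(outside)))
        rows.append((str(ct), len(members), float(res.statistic), p, -np.log10(p), direction))
    out = pd.DataFrame(
        rows, columns=["cell_type", "n_markers", "D", "p", "neg_log10_p", "direction"]
    )
    return out.sort_values("neg_log10_p", ascending=False).reset_index(drop=True)


def pca_project(
    train: pd.DataFrame,
    markers: pd.DataFrame,
    new_samples: pd.DataFrame,
    p_adj_max: float = 0.1,
    lfc_min: float = 0.0,
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit PCA on training samples restricted to passing marker genes and
    project new samples with the training centering.

    ``train`` and ``new_samples`` are genes x samples log-scale matrices.
    """
    passing = markers[(markers["p_adj"] < p_adj_max) & (markers["avg_log2fc"] > lfc_min)]
    genes = sorted(set(passing["gene"]) & set(train.index))
    if not genes:
        raise ValueError("no marker genes pass the filter in the training matrix")
    missing = sorted(set(genes) - set(new_samples.index))
    if missing:
        raise ValueError(f"new samples lack marker genes: {missing[:10]}")
    Xt = train.loc[genes].to_numpy().T
    Xn = new_samples.loc[genes].to_numpy().T
    center = Xt.mean(axis=0)
    k = min(n_components, Xt.shape[0] - 1, Xt.shape[1])
    pca = PCA(n_components=k, random_state=0)
    train_scores = pca.fit_transform(Xt - center)
    new_scores = (Xn - center) @ pca.components_.T
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(train_scores, index=train.columns, columns=cols),
        pd.DataFrame(new_scores, index=new_samples.columns, columns=cols),
    )


def concordance(fc_a: pd.Series, fc_b: pd.Series) -> dict:
    """Cross-modality fold-change agreement.

    Spearman rho over shared genes plus a 2x2 sign-agreement table
    (zero fold changes excluded), its sample odds ratio, and the
    two-sided Fisher p value.
    """
    shared = fc_a.dropna().index.intersection(fc_b.dropna().index)
    if len(shared) < 10:
        warnings.warn(f"only {len(shared)} shared genes for concordance")
    a = fc_a.loc[shared].to_numpy(dtype=float)
    b = fc_b.loc[shared].to_numpy(dtype=float)
    rho = float(st.spearmanr(a, b).statistic) if len(shared) > 1 else np.nan
    nz = (a != 0) & (b != 0)
    up_up = int(np.sum((a[nz] > 0) & (b[nz] > 0)))
    up_dn = int(np.sum((a[nz] > 0) & (b[nz] < 0)))
    dn_up = int(np.sum((a[nz] < 0) & (b[nz] > 0)))
    dn_dn = int(np.sum((a[nz] < 0) & (b[nz] < 0)))
    table = np.array([[up_up, up_dn], [dn_up, dn_dn]])
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (up_up * dn_dn) / (up_dn * dn_up) if up_dn * dn_up > 0 else np.inf
    _, fisher_p = st.fisher_exact(table, alternative="two-sided")
    return {
        "spearman_rho": rho,
        "sign_table": table,
        "odds_ratio": float(odds),
        "fisher_p": float(fisher_p),
        "n_shared": int(len(shared)),
    }


def upstream_regulator_z(
    fold_changes: pd.Series,
    network: Mapping[str, Iterable[tuple[str, int]]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Sign-consistency activation z-scores for candidate upstream regulators.

    For each regulator, targets with nonzero observed fold change are
    scored: z = (agree - disagree) / sqrt(agree + disagree).  The overlap p
    value is the hypergeometric tail of the regulated-target overlap
    against the universe.  A regulator is called activated iff z > 2 and
    -log10(p) > 7, inhibited iff z < -2 with the same p rule, else
    undetermined.
    """
    universe = set(universe)
    fc = fold_changes.reindex(sorted(universe)).fillna(0.0)
    regulated = set(fc.index[fc != 0])
    N, n_reg = len(universe), len(regulated)
    rows = []
    for regulator, targets in network.items():
        targets = [(t, s) for t, s in targets]
        bad = {t for t, _ in targets} - universe
        if bad:
            raise ValueError(f"regulator {regulator!r} has targets outside the universe: {sorted(bad)[:5]}")
        scored = [(t, s) for t, s in targets if fc.get(t, 0.0) != 0.0]
        K = len(targets)
        k = len(scored)
        if k == 0:
            rows.append((regulator, np.nan, 1.0, 0.0, 0, "undetermined"))
            continue
        agree = sum(1 for t, s in scored if np.sign(fc[t]) * s > 0)
        disagree = k - agree
        z = (agree - disagree) / np.sqrt(k)
        overlap_p = float(st.hypergeom.sf(k - 1, N, K, n_reg))
        neglog = -np.log10(max(overlap_p, 1e-300))
        state = "undetermined"
        if neglog > ACTIVATION_NEGLOG10_P:
            if z > ACTIVATION_Z:
                state = "activated"
            elif z < -ACTIVATION_Z:
                state = "inhibited"
        rows.append((regulator, float(z), overlap_p, float(neglog), k, state))
    return pd.DataFrame(
        rows, columns=["regulator", "z", "overlap_p", "neg_log10_overlap_p", "n_scored", "state"]
    )
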