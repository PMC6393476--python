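"""Transcriptional-noise quantification for aging single-cell data.

Two per-cell-type noise measures are implemented:

* **euclidean** — after equalizing sequencing depth (per-cell downsampling
  to the minimum total) and group sizes (equal numbers of young and old
  cells), expression is restricted to mean-stable, low-CV "invariant"
  genes, square-root transformed, and each cell's euclidean distance to
  its (cell type, age) mean is the noise value;
* **spearman** — 1 minus the Spearman correlation across all genes for
  every unordered cell pair within a (cell type, age) group.

Old-vs-young differences are assessed per cell type with a two-sided
rank-sum test, BH-adjusted across cell types, and summarized as
old/young noise ratios at the cell level and after per-mouse averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st

from ._stats import bh_adjust, rank_sum_test
from .containers import CountMatrix


@dataclass
class NoiseConfig:
    n_bins: int = 10
    cv_fraction: float = 0.10
    min_cells_per_group: int = 10
    seed: int = 0
    #: apply depth/group equalization to the pairwise Spearman metric too
    equalize_for_spearman: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValueError("n_bins must be >= 3")
        if not 0 < self.cv_fraction <= 1:
            raise ValueError("cv_fraction must lie in (0, 1]")


def equalize_depth(matrix: CountMatrix, seed: int = 0) -> CountMatrix:
    """Downsample every cell to the minimum total UMI count.

    Per cell, the retained molecules are a without-replacement draw from
    the cell's molecule multiset, so each gene's subsampled count is
    multivariate-hypergeometric and bounded by the original count.
    """
    totals = matrix.column_totals()
    zero = [b for b, t in zip(matrix.barcode_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"cells with zero total UMI cannot be depth-equalized: {zero[:5]}")
    target = int(totals.min())
    rng = np.random.default_rng(seed)
    dense = np.asarray(matrix.values.todense(), dtype=np.int64)
    out = np.empty_like(dense)
    for j in range(dense.shape[1]):
        if totals[j] == target:
            out[:, j] = dense[:, j]
        else:
            out[:, j] = rng.multivariate_hypergeometric(dense[:, j], target)
    return CountMatrix(sp.csr_matrix(out), matrix.gene_ids, matrix.barcode_ids)


def equalize_groups(
    barcodes: list[str],
    cell_type: np.ndarray,
    age: np.ndarray,
    seed: int = 0,
    min_cells_per_group: int = 10,
) -> tuple[list[str], list[str]]:
    """Subsample the larger age group per cell type to the smaller's size.

    Returns the retained barcodes and the list of cell types excluded for
    failing the minimum-cells-per-age rule.
    """
    cell_type = np.asarray(cell_type, dtype=object)
    age = np.asarray(age, dtype=object)
    barcodes = np.asarray(barcodes, dtype=object)
    rng = np.random.default_rng(seed)
    retained: list[str] = []
    excluded: list[str] = []
    for ct in pd.unique(cell_type[~pd.isna(cell_type)]):
        young = np.flatnonzero((cell_type == ct) & (age == "young"))
        old = np.flatnonzero((cell_type == ct) & (age == "old"))
        n = min(young.size, old.size)
        if n < min_cells_per_group:
            excluded.append(str(ct))
            continue
        for idx in (young, old):
            keep = idx if idx.size == n else rng.choice(idx, size=n, replace=False)
            retained.extend(barcodes[np.sort(keep)])
    return retained, excluded


def select_invariant_genes(
    matrix: CountMatrix | np.ndarray,
    config: NoiseConfig | None = None,
    gene_ids: list[str] | None = None,
) -> list[str]:
    """Low-CV genes from the interior mean-expression bins.

    Positive-mean genes are sorted by mean expression (gene id breaks
    ties), split into ``n_bins`` equal-size bins, the extreme bins are
    dropped, and the lowest-CV ``ceil(cv_fraction * bin size)`` genes per
    remaining bin are kept (CV ties again broken by gene id).
    """
    config = config or NoiseConfig()
    if isinstance(matrix, CountMatrix):
        dense = np.asarray(matrix.values.todense(), dtype=float)
        gene_ids = matrix.gene_ids
    else:
        dense = np.asarray(matrix, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(dense.shape[0])]
    means = dense.mean(axis=1)
    sds = dense.std(axis=1, ddof=0)
    positive = np.flatnonzero(means > 0)
    if positive.size == 0:
        raise ValueError("all-zero matrix: no positive-mean genes")
    if positive.size < config.n_bins:
        raise ValueError(
            f"need at least n_bins={config.n_bins} positive-mean genes, have {positive.size}"
        )
    order = sorted(positive, key=lambda i: (means[i], gene_ids[i]))
    bins = np.array_split(np.asarray(order), config.n_bins)
    selected: list[str] = []
    for b in bins[1:-1]:
        take = int(np.ceil(config.cv_fraction * b.size))
        chosen = sorted(b.tolist(), key=lambda i: (sds[i] / means[i], gene_ids[i]))[:take]
        selected.extend(gene_ids[i] for i in chosen)
    return selected


def noise_euclidean(
    matrix: CountMatrix,
    cell_type: np.ndarray,
    age: np.ndarray,
) -> pd.DataFrame:
    """Per-cell distance to the (cell type, age) mean of sqrt counts."""
    cell_type = np.asarray(cell_type, dtype=object)
    age = np.asarray(age, dtype=object)
    sqrt = np.sqrt(np.asarray(matrix.values.todense(), dtype=float))
    rows = []
    for (ct, a), idx in pd.DataFrame({"ct": cell_type, "age": age}).groupby(["ct", "age"]).groups.items():
        idx = np.asarray(idx)
        if idx.size == 1:
            warnings.warn(f"group ({ct}, {a}) has a single cell; its distance is 0")
        group = sqrt[:, idx]
        center = group.mean(axis=1, keepdims=True)
        dist = np.sqrt(((group - center) ** 2).sum(axis=0))
        for j, d in zip(idx, dist):
            rows.append((matrix.barcode_ids[j], str(ct), str(a), float(d)))
    return pd.DataFrame(rows, columns=["barcode", "cell_type", "age", "noise"])


def noise_spearman(
    matrix: CountMatrix,
    cell_type: np.ndarray,
    age: np.ndarray,
) -> pd.DataFrame:
    """1 - Spearman correlation for every unordered within-group cell pair.

    Uses all genes.  Pairs involving a constant expression vector have an
    undefined correlation and are recorded as missing.
    """
    cell_type = np.asarray(cell_type, dtype=object)
    age = np.asarray(age, dtype=object)
    dense = np.asarray(matrix.values.todense(), dtype=float)
    rows = []
    for (ct, a), idx in pd.DataFrame({"ct": cell_type, "age": age}).groupby(["ct", "age"]).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            continue
        group = dense[:, idx]
        ranks = st.rankdata(group, axis=0)
        constant = ranks.std(axis=0) == 0
        if constant.any():
            warnings.warn(f"group ({ct}, {a}) has constant cells; their pairs are missing")
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(ranks.T)
        for u in range(idx.size):
            for v in range(u + 1, idx.size):
                value = np.nan if (constant[u] or constant[v]) else 1.0 - corr[u, v]
                rows.append(
                    (
                        matrix.barcode_ids[idx[u]],
                        matrix.barcode_ids[idx[v]],
                        str(ct),
                        str(a),
                        value,
                    )
                )
    return pd.DataFrame(rows, columns=["barcode_a", "barcode_b", "cell_type", "age", "noise"])


def noise_test(
    values: pd.DataFrame,
    mouse_of: pd.Series | None = None,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Per-cell-type old-vs-young rank-sum tests on noise values.

    ``values`` is the output of :func:`noise_euclidean` or
    :func:`noise_spearman`; ``mouse_of`` maps barcode to mouse id for the
    per-mouse-averaged ratio.  BH adjustment runs across cell types.
    """
    rows = []
    for ct, sub in values.groupby("cell_type"):
        old = sub.loc[sub["age"] == "old", "noise"].dropna().to_numpy()
        young = sub.loc[sub["age"] == "young", "noise"].dropna().to_numpy()
        if old.size == 0 or young.size == 0:
            continue
        stat, p = rank_sum_test(old, young)
        young_mean = young.mean()
        ratio = old.mean() / young_mean if young_mean > 0 else np.nan
        if not np.isfinite(ratio):
            warnings.warn(f"cell type {ct!r} has zero young mean; ratio missing")
        mouse_ratio = np.nan
        if mouse_of is not None:
            mouse_ratio = _mouse_level_ratio(sub, mouse_of, metric)
        rows.append(
            (
                str(ct), metric, float(stat), float(p),
                float(ratio), float(np.log2(ratio)) if ratio and ratio > 0 else np.nan,
                float(mouse_ratio),
                float(np.log2(mouse_ratio)) if np.isfinite(mouse_ratio) and mouse_ratio > 0 else np.nan,
                int(young.size), int(old.size),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "cell_type", "metric", "W", "p", "ratio_old_over_young", "log2_ratio",
            "mouse_level_ratio", "mouse_level_log2_ratio", "n_young", "n_old",
        ],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def _mouse_level_ratio(sub: pd.DataFrame, mouse_of: pd.Series, metric: str) -> float:
    if metric == "euclidean":
        per = sub.assign(mouse=sub["barcode"].map(mouse_of))
    else:
        # a pair has a unique mouse only when both cells share one
        same = sub["barcode_a"].map(mouse_of) == sub["barcode_b"].map(mouse_of)
        per = sub[same].assign(mouse=sub.loc[same, "barcode_a"].map(mouse_of))
        if per.empty:
            return np.nan
    means = per.groupby(["age", "mouse"])["noise"].mean()
    try:
        young = means.loc["young"].mean()
        old = means.loc["old"].mean()
    except KeyError:
        return np.nan
    return old / young if young > 0 else np.nan


def run_noise_pipeline(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    config: NoiseConfig | None = None,
    metrics: tuple[str, ...] = ("euclidean", "spearman"),
) -> dict[str, pd.DataFrame]:
    """Full noise analysis: equalize, select genes per cell type, measure, test.

    ``annotation`` needs barcode, mouse_id, age and cell_type columns for
    the real cells.  Returns per-metric per-cell (or per-pair) noise values
    and the combined per-cell-type report.
    """
    config = config or NoiseConfig()
    ann = annotation.dropna(subset=["cell_type"]).set_index("barcode")
    cells = matrix.subset_barcodes(list(ann.index))
    equalized = equalize_depth(cells, seed=config.seed)
    retained, excluded = equalize_groups(
        equalized.barcode_ids,
        ann["cell_type"].to_numpy(),
        ann["age"].to_numpy(),
        seed=config.seed + 1,
        min_cells_per_group=config.min_cells_per_group,
    )
    eq = equalized.subset_barcodes(retained)
    sub_ann = ann.loc[retained]
    mouse_of = sub_ann["mouse_id"]

    results: dict[str, pd.DataFrame] = {"excluded_cell_types": pd.DataFrame({"cell_type": excluded})}
    reports = []
    for metric in metrics:
        per_type = []
        for ct in pd.unique(sub_ann["cell_type"]):
            sel = np.flatnonzero((sub_ann["cell_type"] == ct).to_numpy())
            type_matrix = eq.subset_barcodes([retained[i] for i in sel])
            ages = sub_ann["age"].to_numpy()[sel]
            types = sub_ann["cell_type"].to_numpy()[sel]
            if metric == "euclidean":
                genes = select_invariant_genes(type_matrix, config)
                per_type.append(noise_euclidean(type_matrix.subset_genes(genes), types, ages))
            elif metric == "spearman":
                source = type_matrix if config.equalize_for_spearman else matrix.subset_barcodes(type_matrix.barcode_ids)
                per_type.append(noise_spearman(source, types, ages))
            else:
                raise ValueError(f"unknown metric {metric!r}")
        values = pd.concat(per_type, ignore_index=True)
        results[f"noise_{metric}"] = values
        reports.append(noise_test(values, mouse_of=mouse_of, metric=metric))
    results["report"] = pd.concat(reports, ignore_index=True)
    return results
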