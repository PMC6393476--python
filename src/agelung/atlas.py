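"""Cell calling, consensus feature selection, embedding/clustering, and
marker/signature machinery for the droplet atlas.

The cell-calling rule keeps barcodes that are simultaneously within the top
``max_barcodes`` by total UMI count and detect more than ``min_genes`` genes;
everything else forms the empty-droplet pool that feeds ambient-mRNA
detection.  Feature selection is a consensus over per-mouse highly variable
genes so that cell-type discovery is not confounded by age effects, followed
by an independent-component embedding and graph-community clustering.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from ._stats import bh_adjust, log_normalize, normalized_counts, ranksum_matrix
from .containers import CountMatrix, Embedding

FOLD_CHANGE_EPS = 1e-9

MARKER_COLUMNS = ("gene", "cell_type", "avg_log2fc", "pct_in", "pct_out", "p", "p_adj")


class CellCalls(NamedTuple):
    cells: list[str]
    empty_pool: list[str]


def call_cells(
    column_totals: Mapping[str, int] | pd.Series,
    genes_detected: Mapping[str, int] | pd.Series,
    max_barcodes: int = 1200,
    min_genes: int = 200,
) -> CellCalls:
    """Apply the barcode-rank cell-calling rule.

    A barcode is called a cell iff it lies within the top ``max_barcodes``
    barcodes by total UMI count (ties at the cutoff total are all kept) and
    has strictly more than ``min_genes`` genes detected.  Output order is a
    deterministic function of the rule, not of input order.
    """
    totals = pd.Series(column_totals, dtype=float)
    genes = pd.Series(genes_detected, dtype=float)
    if not totals.index.equals(genes.index):
        genes = genes.reindex(totals.index)
        if genes.isna().any():
            raise ValueError("column_totals and genes_detected must cover the same barcodes")
    if len(totals) < max_barcodes:
        warnings.warn(
            f"only {len(totals)} barcodes available for a top-{max_barcodes} rule; using all"
        )
        in_top = pd.Series(True, index=totals.index)
    else:
        cutoff = totals.sort_values(ascending=False).iloc[max_barcodes - 1]
        in_top = totals >= cutoff
    kept = in_top & (genes > min_genes)
    order = totals.sort_values(ascending=False, kind="mergesort").index
    cells = [b for b in order if kept[b]]
    empty_pool = [b for b in order if not kept[b]]
    return CellCalls(cells, empty_pool)


def per_mouse_hvg(
    matrix: CountMatrix,
    n_bins: int = 20,
    min_disp: float = 0.5,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
) -> set[str]:
    """Highly variable genes of one mouse (binned dispersion z-score)."""
    import scanpy as sc

    adata = matrix.to_anndata()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            adata, flavor="seurat", n_bins=n_bins,
            min_disp=min_disp, min_mean=min_mean, max_mean=max_mean,
        )
    X = adata.X
    dense = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    nonconstant = dense.var(axis=0) > 0  # a constant gene is never variable
    return set(adata.var.index[adata.var["highly_variable"].to_numpy() & nonconstant])


def consensus_hvg(
    per_mouse_matrices: Mapping[str, CountMatrix],
    min_samples: int = 4,
    cell_cycle_genes: Iterable[str] = (),
    **hvg_kwargs,
) -> set[str]:
    """Genes highly variable in strictly more than ``min_samples`` mice,
    with cell-cycle genes removed."""
    if len(per_mouse_matrices) < 2:
        raise ValueError("consensus HVG needs at least two mice")
    universes = [set(m.gene_ids) for m in per_mouse_matrices.values()]
    shared = set.intersection(*universes)
    if not shared:
        raise ValueError("per-mouse matrices share no genes")
    counts: dict[str, int] = {}
    for m in per_mouse_matrices.values():
        for g in per_mouse_hvg(m, **hvg_kwargs):
            counts[g] = counts.get(g, 0) + 1
    consensus = {g for g, c in counts.items() if c > min_samples and g in shared}
    return consensus - set(cell_cycle_genes)


def normalize_and_embed(
    matrix: CountMatrix,
    hvg: Iterable[str],
    k: int = 30,
    seed: int = 0,
) -> Embedding:
    """Library-size normalize, log1p, regress out total UMI, scale, then ICA.

    Component sign is fixed by making each component's largest-magnitude
    gene loading positive, and components are ordered by decreasing source
    variance before scaling, so runs with the same seed agree exactly.
    """
    import scanpy as sc
    from sklearn.decomposition import FastICA

    hvg = sorted(set(hvg))
    missing = set(hvg) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"HVG not in gene universe: {sorted(missing)[:5]}")
    if k < 2 or k > len(hvg):
        raise ValueError(f"k={k} must lie in [2, |hvg|={len(hvg)}]")
    adata = matrix.to_anndata()
    adata.obs["total_counts"] = matrix.column_totals()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    adata = adata[:, hvg].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.regress_out(adata, ["total_counts"])
        sc.pp.scale(adata)
    X = np.asarray(adata.X, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica = FastICA(n_components=k, random_state=seed, max_iter=1000, whiten="unit-variance")
        sources = ica.fit_transform(X)
    loadings = ica.components_  # k x genes
    flip = np.sign(loadings[np.arange(k), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    sources = sources * flip
    order = np.argsort(-sources.var(axis=0), kind="stable")
    sources = sources[:, order]
    return Embedding(sources, method="ica", k=k, seed=seed, barcode_ids=matrix.barcode_ids)


def scaled_expression(matrix: CountMatrix, genes: Iterable[str]) -> np.ndarray:
    """Cells x genes matrix after the normalize/log/scale pipeline (no ICA)."""
    sub = matrix.subset_genes(sorted(set(genes)))
    logged = log_normalize(sub.values)
    centered = logged - logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (centered / sd).T


def cluster_cells(
    embedding: Embedding,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Graph-community labels from a kNN graph on the embedding.

    Modularity optimization (Louvain objective with resolution) via the
    seeded Leiden refinement, which makes the partition reproducible.
    """
    import igraph
    import leidenalg

    coords = embedding.coords
    n = coords.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least two cells")
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)


def batch_silhouette(embedding: Embedding, mouse_ids: Iterable[str]) -> float:
    """Mean silhouette of cells with mouse identity as the cluster label.

    Values near zero mean the embedding carries no mouse-of-origin
    structure (good mixing).  Cells from a single-cell mouse and cells in
    0/0-degenerate configurations contribute 0.
    """
    labels = np.asarray(list(mouse_ids), dtype=object)
    if len(set(labels.tolist())) < 2:
        raise ValueError("batch silhouette needs at least two mice")
    sizes = pd.Series(labels).value_counts()
    if (sizes == 1).any():
        warnings.warn("mice with a single cell contribute silhouette 0")
    codes = pd.factorize(labels)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = silhouette_samples(embedding.coords, codes)
    values = np.nan_to_num(values)
    return float(values.mean())


def find_markers(
    matrix: CountMatrix,
    labels: Iterable[str],
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table per label.

    p values come from the rank-sum test on log-normalized expression;
    ``avg_log2fc`` compares library-size-normalized group means with a
    pseudocount; BH adjustment is applied within each label.
    """
    labels = np.asarray(list(labels), dtype=object)
    if labels.size != matrix.n_barcodes:
        raise ValueError("labels must align with barcodes")
    unique = [l for l in pd.unique(labels) if not pd.isna(l)]
    if len(unique) < 2:
        raise ValueError("need at least two labels")
    logged = log_normalize(matrix.values)
    normed = normalized_counts(matrix.values)
    detected = np.asarray((matrix.values > 0).todense())
    rows = []
    for label in unique:
        in_group = labels == label
        if in_group.sum() < min_cells:
            warnings.warn(f"label {label!r} has fewer than {min_cells} cells; skipped")
            continue
        p = ranksum_matrix(logged, in_group)
        mean_in = normed[:, in_group].mean(axis=1)
        mean_out = normed[:, ~in_group].mean(axis=1)
        lfc = np.log2(mean_in + FOLD_CHANGE_EPS) - np.log2(mean_out + FOLD_CHANGE_EPS)
        rows.append(
            pd.DataFrame(
                {
                    "gene": matrix.gene_ids,
                    "cell_type": label,
                    "avg_log2fc": lfc,
                    "pct_in": detected[:, in_group].mean(axis=1),
                    "pct_out": detected[:, ~in_group].mean(axis=1),
                    "p": p,
                    "p_adj": bh_adjust(p),
                }
            )
        )
    if not rows:
        raise ValueError("no label had enough cells")
    return pd.concat(rows, ignore_index=True)


def signature_fisher(
    query_markers: Mapping[str, Iterable[str]],
    reference_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided (greater) Fisher enrichment of query vs reference sets.

    Gene symbols are capitalized on both sides (mouse symbols map to their
    human counterparts by capitalization).  BH adjustment across all
    (query, reference) pairs.
    """
    universe = {str(g).upper() for g in universe}
    if not universe:
        raise ValueError("empty universe")
    queries = {name: {str(g).upper() for g in genes} & universe for name, genes in query_markers.items()}
    references = {name: {str(g).upper() for g in genes} & universe for name, genes in reference_sets.items()}
    N = len(universe)
    rows = []
    for qname, q in queries.items():
        for rname, r in references.items():
            overlap = len(q & r)
            table = [
                [overlap, len(q) - overlap],
                [len(r) - overlap, N - len(q) - len(r) + overlap],
            ]
            _, p = st.fisher_exact(table, alternative="greater")
            rows.append((qname, rname, overlap, len(q), len(r), p))
    out = pd.DataFrame(
        rows, columns=["query", "reference", "overlap", "query_size", "reference_size", "p"]
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def filter_markers(
    markers: pd.DataFrame, p_adj_max: float = 0.1, lfc_min: float = 1.0
) -> dict[str, set[str]]:
    """Marker sets per cell type after the significance/fold-change filter."""
    passing = markers[(markers["p_adj"] < p_adj_max) & (markers["avg_log2fc"] > lfc_min)]
    return {str(ct): set(sub["gene"]) for ct, sub in passing.groupby("cell_type")}


def signature_match(
    markers_a: pd.DataFrame,
    markers_b: pd.DataFrame,
    p_adj_max: float = 0.1,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Jaccard matrix between threshold-filtered marker sets of two tables."""
    sets_a = filter_markers(markers_a, p_adj_max, lfc_min)
    sets_b = filter_markers(markers_b, p_adj_max, lfc_min)
    types_a = sorted(set(markers_a["cell_type"].astype(str)))
    types_b = sorted(set(markers_b["cell_type"].astype(str)))
    out = pd.DataFrame(0.0, index=types_a, columns=types_b)
    for ta in types_a:
        a = sets_a.get(ta, set())
        if not a:
            warnings.warn(f"cluster {ta!r} has no passing markers")
        for tb in types_b:
            b = sets_b.get(tb, set())
            union = len(a | b)
            out.loc[ta, tb] = len(a & b) / union if union else 0.0
    return out
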