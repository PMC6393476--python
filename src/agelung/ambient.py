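"""Ambient mRNA detection and ambient-aware cell-type-resolved age DE.

Free transcripts from lysed cells end up in every droplet, so genes that
dominate the ambient pool look ubiquitously expressed.  The detector reads
gene identities off barcodes at the tail of the total-UMI distribution
(mean ~10 UMIs, i.e. beads that never met a cell).  Detected ambient genes
are then split into constitutive housekeepers (no cell-type-specific
expression; removed from age testing everywhere) and restricted genes that
may only be age-tested in the cell types where they show genuine
cell-type-specific expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, log_normalize, normalized_counts, ranksum_matrix
from .atlas import FOLD_CHANGE_EPS
from .containers import CountMatrix

MASK_HOUSEKEEPER = "housekeeper"
MASK_NOT_SPECIFIC = "ambient_not_specific"


@dataclass
class AmbientReport:
    """Partition of detected ambient genes and empty-pool QC numbers."""

    ambient_genes: set[str]
    housekeepers: set[str] = field(default_factory=set)
    #: restricted gene -> cell types where age testing is allowed
    restricted: dict[str, set[str]] = field(default_factory=dict)
    empty_barcode_count: int = 0
    mean_empty_umi: float = float("nan")

    def __post_init__(self) -> None:
        restricted = set(self.restricted)
        if self.housekeepers | restricted != self.ambient_genes or self.housekeepers & restricted:
            if self.housekeepers or self.restricted:
                raise ValueError("housekeepers and restricted must partition ambient_genes")

    def mask_reason(self, gene: str, cell_type: str) -> str | None:
        """None if (gene, cell_type) may be age-tested, else the reason."""
        if gene not in self.ambient_genes:
            return None
        if gene in self.housekeepers:
            return MASK_HOUSEKEEPER
        if cell_type in self.restricted.get(gene, set()):
            return None
        return MASK_NOT_SPECIFIC

    def to_json(self) -> dict:
        return {
            "ambient_genes": sorted(self.ambient_genes),
            "housekeepers": sorted(self.housekeepers),
            "restricted": {g: sorted(cts) for g, cts in sorted(self.restricted.items())},
            "empty_barcode_count": self.empty_barcode_count,
            "mean_empty_umi": self.mean_empty_umi,
        }


def detect_ambient(
    raw_matrix: CountMatrix,
    cell_barcodes: set[str] | list[str],
    empty_window: tuple[int, int] = (5, 15),
    presence_fraction: float = 0.25,
    min_window_barcodes: int = 100,
) -> AmbientReport:
    """Call ambient genes from empty-droplet presence fractions.

    A gene is ambient iff it is detected (count >= 1) in at least
    ``presence_fraction`` of the non-cell barcodes whose total UMI count
    falls inside ``empty_window``.  The report carries the mean empty-pool
    UMI total as a QC check against the ~10-UMI expectation.
    """
    cells = set(cell_barcodes)
    totals = raw_matrix.column_totals()
    lo, hi = empty_window
    in_window = np.array(
        [(b not in cells) and lo <= t <= hi for b, t in zip(raw_matrix.barcode_ids, totals)]
    )
    n_window = int(in_window.sum())
    if n_window < min_window_barcodes:
        raise ValueError(
            f"empty window {empty_window} matched only {n_window} barcodes "
            f"(< {min_window_barcodes}); ambient estimate would be unstable"
        )
    sub = raw_matrix.values[:, np.flatnonzero(in_window)]
    presence = np.asarray((sub > 0).sum(axis=1)).ravel() / n_window
    ambient = {g for g, f in zip(raw_matrix.gene_ids, presence) if f >= presence_fraction}
    return AmbientReport(
        ambient_genes=ambient,
        empty_barcode_count=n_window,
        mean_empty_umi=float(totals[in_window].mean()),
    )


def split_housekeepers(
    ambient_genes: set[str],
    markers: pd.DataFrame,
    lfc_threshold: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Split ambient genes into housekeepers and cell-type-restricted genes.

    A gene is a constitutive housekeeper iff its maximum cell-type marker
    log2 fold change stays below ``lfc_threshold``; genes absent from the
    marker table count as having no specific effect (log2FC 0).
    """
    max_lfc = markers.groupby("gene")["avg_log2fc"].max()
    housekeepers, restricted = set(), set()
    for gene in ambient_genes:
        if float(max_lfc.get(gene, 0.0)) < lfc_threshold:
            housekeepers.add(gene)
        else:
            restricted.add(gene)
    return housekeepers, restricted


def de_test_mask(
    restricted: set[str],
    markers: pd.DataFrame,
    p_adj_max: float = 0.25,
) -> dict[str, set[str]]:
    """Cell types where each restricted ambient gene may be age-tested.

    A restricted gene is testable in a cell type iff its marker adjusted p
    value there is below ``p_adj_max`` (moderate cell-type-specific
    expression).  Housekeepers are testable nowhere and non-ambient genes
    everywhere; both are encoded by :meth:`AmbientReport.mask_reason`.
    """
    allowed: dict[str, set[str]] = {g: set() for g in restricted}
    sub = markers[markers["gene"].isin(restricted) & (markers["p_adj"] < p_adj_max)]
    for gene, rows in sub.groupby("gene"):
        allowed[str(gene)] = set(rows["cell_type"].astype(str))
    return allowed


def build_ambient_report(
    raw_matrix: CountMatrix,
    cell_barcodes: set[str] | list[str],
    markers: pd.DataFrame,
    empty_window: tuple[int, int] = (5, 15),
    presence_fraction: float = 0.25,
    lfc_threshold: float = 1.0,
    p_adj_max: float = 0.25,
) -> AmbientReport:
    """Detection plus housekeeper/restricted partition in one pass."""
    report = detect_ambient(raw_matrix, cell_barcodes, empty_window, presence_fraction)
    housekeepers, restricted = split_housekeepers(report.ambient_genes, markers, lfc_threshold)
    report.housekeepers = housekeepers
    report.restricted = de_test_mask(restricted, markers, p_adj_max)
    return report


def age_de_per_celltype(
    matrix: CountMatrix,
    cell_types: np.ndarray,
    age: np.ndarray,
    mask: AmbientReport | None = None,
    min_cells_per_age: int = 3,
) -> pd.DataFrame:
    """Old-vs-young rank-sum DE within each cell type, ambient-masked.

    Returns one row per (gene, cell type) with ``tested`` flags; masked
    rows keep no p value and carry a ``mask_reason``.  BH adjustment is
    applied within each cell type over the tested genes only.
    """
    cell_types = np.asarray(cell_types, dtype=object)
    age = np.asarray(age, dtype=object)
    if cell_types.size != matrix.n_barcodes or age.size != matrix.n_barcodes:
        raise ValueError("cell_types and age must align with barcodes")
    logged = log_normalize(matrix.values)
    normed = normalized_counts(matrix.values)
    frames = []
    for ct in pd.unique(cell_types[~pd.isna(cell_types)]):
        sel = cell_types == ct
        is_old = age == "old"
        n_old = int((sel & is_old).sum())
        n_young = int((sel & ~is_old).sum())
        if min(n_old, n_young) < min_cells_per_age:
            warnings.warn(
                f"cell type {ct!r} has {n_young} young / {n_old} old cells; skipped"
            )
            continue
        reasons = (
            [mask.mask_reason(g, str(ct)) for g in matrix.gene_ids]
            if mask is not None
            else [None] * matrix.n_genes
        )
        testable = np.array([r is None for r in reasons])
        sub_logged = logged[:, sel]
        p = np.full(matrix.n_genes, np.nan)
        if testable.any():
            p[testable] = ranksum_matrix(sub_logged[testable], is_old[sel])
        mean_old = normed[:, sel & is_old].mean(axis=1)
        mean_young = normed[:, sel & ~is_old].mean(axis=1)
        lfc = np.log2(mean_old + FOLD_CHANGE_EPS) - np.log2(mean_young + FOLD_CHANGE_EPS)
        frames.append(
            pd.DataFrame(
                {
                    "gene": matrix.gene_ids,
                    "cell_type": str(ct),
                    "avg_log2fc": lfc,
                    "p": p,
                    "p_adj": bh_adjust(p),
                    "tested": testable,
                    "mask_reason": [r if r is not None else pd.NA for r in reasons],
                }
            )
        )
    if not frames:
        raise ValueError("no cell type satisfied the per-age group-size floor")
    return pd.concat(frames, ignore_index=True)
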