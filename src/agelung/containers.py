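"""Shared in-memory containers for the atlas pipeline.

The universal single-cell currency here is :class:`CountMatrix`, a sparse
genes x barcodes matrix of raw UMI counts together with ordered id lists.
Cell-level metadata travels as a plain :class:`pandas.DataFrame` (one row per
barcode) so it can be written to and read from TSV without ceremony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

ANNOTATION_COLUMNS = ("barcode", "mouse_id", "age", "cell_type", "total_umi", "genes_detected")
AGES = ("young", "old")


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, genes x barcodes."""

    values: sp.csr_matrix
    gene_ids: list[str]
    barcode_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = list(self.gene_ids)
        self.barcode_ids = list(self.barcode_ids)
        n_genes, n_barcodes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows")
        if len(self.barcode_ids) != n_barcodes:
            raise ValueError(f"{len(self.barcode_ids)} barcode ids for {n_barcodes} matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.barcode_ids)) != n_barcodes:
            raise ValueError("barcode_ids are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix has negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.values.shape[1]

    def column_totals(self) -> np.ndarray:
        """Total UMI count per barcode."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with at least one count, per barcode."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def subset_barcodes(self, barcodes: list[str] | np.ndarray) -> "CountMatrix":
        index = {b: i for i, b in enumerate(self.barcode_ids)}
        cols = np.array([index[b] for b in barcodes], dtype=int)
        return CountMatrix(self.values[:, cols], self.gene_ids, list(barcodes))

    def subset_genes(self, genes: list[str] | np.ndarray) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = np.array([index[g] for g in genes], dtype=int)
        return CountMatrix(self.values[rows, :], list(genes), self.barcode_ids)

    def to_anndata(self):
        """Cells x genes AnnData view (scanpy orientation)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.values.T.tocsr().astype(np.float32),
            obs=pd.DataFrame(index=pd.Index(self.barcode_ids, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )
        return adata


@dataclass
class Embedding:
    """A cells x k real-valued embedding with provenance tags."""

    coords: np.ndarray
    method: str
    k: int
    seed: int
    barcode_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite entries")
        if self.coords.shape[1] != self.k:
            raise ValueError("component count does not match coordinate matrix")


def make_annotation(
    matrix: CountMatrix,
    mouse_id: np.ndarray,
    age: np.ndarray,
    cell_type: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble a per-barcode annotation frame aligned with ``matrix``."""
    bad = set(np.unique(age)) - set(AGES)
    if bad:
        raise ValueError(f"age labels must be in {AGES}, got {sorted(bad)}")
    frame = pd.DataFrame(
        {
            "barcode": matrix.barcode_ids,
            "mouse_id": np.asarray(mouse_id, dtype=object),
            "age": np.asarray(age, dtype=object),
            "cell_type": (
                np.asarray(cell_type, dtype=object) if cell_type is not None else pd.NA
            ),
            "total_umi": matrix.column_totals().astype(int),
            "genes_detected": matrix.genes_detected().astype(int),
        }
    )
    return frame
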