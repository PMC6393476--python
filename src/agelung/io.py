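"""Readers and writers for the standard on-disk formats of the pipeline.

Matrix Market coordinate triplets (1-based) with genes.tsv/barcodes.tsv
sidecars for UMI counts, TSV for metadata and count tables, CSV for the
long-format proteome, GMT for gene-set collections, and a simple
(regulator, target, sign) TSV for directional regulator networks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix
from .sim import FRACTIONS, SimTruth, truth_to_json


def write_count_matrix(matrix: CountMatrix, directory: str | Path, prefix: str = "") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        directory / f"{prefix}matrix.mtx", matrix.values.tocoo().astype(np.int64), field="integer"
    )
    (directory / f"{prefix}genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    (directory / f"{prefix}barcodes.tsv").write_text("\n".join(matrix.barcode_ids) + "\n")


def read_count_matrix(directory: str | Path, prefix: str = "") -> CountMatrix:
    directory = Path(directory)
    values = sp.csr_matrix(scipy.io.mmread(directory / f"{prefix}matrix.mtx"))
    genes = (directory / f"{prefix}genes.tsv").read_text().splitlines()
    barcodes = (directory / f"{prefix}barcodes.tsv").read_text().splitlines()
    return CountMatrix(values, genes, barcodes)


def write_fixtures(
    directory: str | Path,
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    truth: SimTruth | None = None,
    bulk: pd.DataFrame | None = None,
    qdsp: pd.DataFrame | None = None,
    tissue: pd.DataFrame | None = None,
) -> None:
    """Write the full synthetic-study fixture set to ``directory``.

    A later :func:`read_count_matrix` round-trip reproduces the sparse
    matrix exactly.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc
    write_count_matrix(matrix, directory)
    annotation.to_csv(directory / "metadata.tsv", sep="\t", index=False)
    if truth is not None:
        (directory / "truth.json").write_text(json.dumps(truth_to_json(truth), indent=1))
    if bulk is not None:
        bulk.to_csv(directory / "bulk.tsv", sep="\t", index_label="gene")
    if qdsp is not None:
        qdsp.to_csv(directory / "proteome.csv", index=False)
    if tissue is not None:
        tissue.to_csv(directory / "tissue_proteome.tsv", sep="\t", index_label="protein_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bulk_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_qdsp_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format proteome CSV and validate fraction labels."""
    table = pd.read_csv(path)
    required = {"protein_id", "age", "replicate", "fraction", "log2_intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"proteome CSV lacks columns: {sorted(missing)}")
    bad = set(table["fraction"].unique()) - set(FRACTIONS)
    if bad:
        raise ValueError(f"unknown solubility fraction labels: {sorted(bad)} (expected {FRACTIONS})")
    return table


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_regulator_network(path: str | Path) -> dict[str, list[tuple[str, int]]]:
    """TSV with columns regulator, target, sign (+1/-1)."""
    table = pd.read_csv(path, sep="\t")
    required = {"regulator", "target", "sign"}
    if not required <= set(table.columns):
        raise ValueError(f"network TSV must have columns {sorted(required)}")
    network: dict[str, list[tuple[str, int]]] = {}
    for reg, sub in table.groupby("regulator"):
        if sub["target"].duplicated().any():
            raise ValueError(f"duplicate targets for regulator {reg}")
        signs = set(sub["sign"].astype(int))
        if not signs <= {-1, 1}:
            raise ValueError(f"regulator {reg} has signs outside {{-1, +1}}")
        network[str(reg)] = list(zip(sub["target"].astype(str), sub["sign"].astype(int)))
    return network
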