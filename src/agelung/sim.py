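"""Synthetic multi-omics generator with known ground truth.

Emulates the statistical structure of a multi-mouse droplet scRNA-seq aging
study together with matched whole-organ bulk RNA-seq and a four-fraction
detergent-solubility proteome:

* a cohort of young and old mice, each contributing a few hundred cells,
* per-cell-type negative-binomial expression (variance mu + alpha * mu^2)
  whose dispersion alpha is inflated multiplicatively in old cells — the
  generative analogue of age-increased transcriptional noise,
* ambient mRNA: every droplet's counts are a cell-derived NB component at
  expected fraction (1 - rho) plus a Poisson ambient component at rho drawn
  from the library-size-weighted average of all cell-type profiles,
* empty droplets that are pure ambient multinomial draws with Poisson totals
  (mean ~10 UMIs, the tail of the barcode-rank distribution),
* age-dependent cell-type composition shifts (a ciliated-like type whose
  proportion doubles by default),
* optional gene-level age effects (cell-type-restricted or global) and an
  mRNA/protein-decoupled gene set reproducing the collagen-IV pattern of
  opposite transcript and protein fold changes,
* a proteome whose log2 abundance tracks the pseudobulk transcriptome with
  slope ``protein_coupling`` plus noise, and whose solubility profiles live
  on the 4-fraction simplex with an age-shifted subset.

Everything is driven by one :class:`SimConfig`; identical configs (same seed)
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, make_annotation

FRACTIONS = ("FR1", "FR2", "FR3", "INSOL")


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic aging-lung study.

    Counts and proportions mirror the study design they emulate: 8 young and
    7 old mice, droplet totals of a few hundred to a few thousand UMIs for
    real cells and ~10 UMIs for empty droplets.
    """

    n_genes: int = 1000
    n_celltypes: int = 10
    mice_young: int = 8
    mice_old: int = 7
    cells_per_mouse: int = 250
    empty_droplets_per_mouse: int = 400
    mean_umi_per_cell: int = 1500
    mean_umi_per_empty: int = 10
    ambient_fraction: float = 0.05
    base_dispersion: float = 0.5
    #: scalar or per-cell-type multipliers applied to alpha in old cells
    old_dispersion_multiplier: float | tuple[float, ...] = 2.0
    composition_young: tuple[float, ...] | None = None
    composition_old: tuple[float, ...] | None = None
    n_markers_per_type: int = 10
    marker_log2fc: float = 3.0
    #: (gene index, cell-type index or None for all types, log2FC in old)
    de_effects: tuple[tuple[int, int | None, float], ...] = ()
    #: (gene index, mRNA log2FC in old, protein log2FC in old)
    decoupled_genes: tuple[tuple[int, float, float], ...] = ()
    housekeeper_genes: tuple[int, ...] = ()
    seed: int = 0

    # --- structural knobs beyond the core design ---
    #: leading block of genes given a dominant, cell-type-uniform share of
    #: the transcriptome (Scgb1a1/Sftpc-like transcripts that feed the
    #: ambient pool); 0 disables
    abundant_genes: int = 0
    abundant_mass: float = 0.6
    baseline_log_sd: float = 1.2
    bulk_dispersion: float = 0.05
    bulk_libsize: float = 2e6
    bulk_libsize_log_sd: float = 0.15
    #: sd of the fixed per-gene log-normal capture bias of the bulk protocol
    bulk_gene_bias_sd: float = 0.4
    proteome_replicates: int = 4
    proteome_sigma: float = 0.25
    protein_coupling: float = 0.6
    solubility_shifted_genes: tuple[int, ...] = ()
    solubility_shift: float = 0.35
    proteome_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_celltypes", "mice_young", "mice_old", "cells_per_mouse",
            "empty_droplets_per_mouse", "mean_umi_per_cell", "mean_umi_per_empty",
            "proteome_replicates",
        ):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if not 0.0 <= self.ambient_fraction < 1.0:
            raise ConfigurationError("ambient_fraction must lie in [0, 1)")
        if self.base_dispersion <= 0:
            raise ConfigurationError("base_dispersion must be positive")
        K = self.n_celltypes
        if self.composition_young is None:
            self.composition_young = tuple(np.full(K, 1.0 / K))
        if self.composition_old is None:
            # default study condition: first cell type doubles its share
            old = np.array(self.composition_young, dtype=float)
            old[0] *= 2.0
            self.composition_old = tuple(old / old.sum())
        for name in ("composition_young", "composition_old"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.size != K:
                raise ConfigurationError(f"{name} must have n_celltypes entries")
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-12:
                raise ConfigurationError(f"{name} must be a probability vector summing to 1")
        mult = np.atleast_1d(np.asarray(self.old_dispersion_multiplier, dtype=float))
        if mult.size == 1:
            mult = np.full(K, mult[0])
        if mult.size != K or np.any(mult <= 0):
            raise ConfigurationError(
                "old_dispersion_multiplier must be a positive scalar or one positive value per cell type"
            )
        self.old_dispersion_multiplier = tuple(mult)
        if self.abundant_genes + self.n_celltypes * self.n_markers_per_type > self.n_genes:
            raise ConfigurationError(
                "n_genes too small for abundant_genes plus disjoint marker blocks"
            )
        if not 0.0 <= self.abundant_mass < 1.0:
            raise ConfigurationError("abundant_mass must lie in [0, 1)")
        for g, _ct, _fc in self.de_effects:
            if not 0 <= g < self.n_genes:
                raise ConfigurationError(f"de_effects references gene index {g} outside the gene universe")
        for g, _m, _p in self.decoupled_genes:
            if not 0 <= g < self.n_genes:
                raise ConfigurationError(f"decoupled_genes references gene index {g} outside the gene universe")


@dataclass
class SimTruth:
    """Ground truth materialized from a :class:`SimConfig` draw."""

    gene_ids: list[str]
    celltype_names: list[str]
    #: genes x cell types per-cell expected expression shares (columns sum to 1)
    profiles_young: np.ndarray
    profiles_old: np.ndarray
    ambient_profile: np.ndarray
    cells: pd.DataFrame  # barcode, mouse_id, age, cell_type (real cells only)
    empty_barcodes: list[str]
    dispersion: dict[tuple[str, str], float]  # (cell type, age) -> alpha
    marker_genes: dict[str, list[int]]
    de_effects: list[tuple[int, int | None, float]]
    decoupled_genes: list[tuple[int, float, float]]
    housekeeper_genes: list[int]
    composition_young: np.ndarray
    composition_old: np.ndarray
    config: SimConfig = field(repr=False, default=None)

    def bulk_expected_profile(self, age: str) -> np.ndarray:
        """Composition-weighted expected expression share per gene."""
        comp = self.composition_young if age == "young" else self.composition_old
        prof = self.profiles_young if age == "young" else self.profiles_old
        mix = prof @ comp
        return mix / mix.sum()

    def bulk_log2fc(self) -> np.ndarray:
        """Expected whole-organ log2 fold change (old vs young) per gene."""
        return np.log2(self.bulk_expected_profile("old") / self.bulk_expected_profile("young"))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _celltype_names(n: int) -> list[str]:
    return [f"T{i:02d}" for i in range(n)]


def _base_profiles(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Young/old genes x cell-types expression-weight matrices (unnormalized)."""
    G, K = config.n_genes, config.n_celltypes
    base = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=G)
    a = config.abundant_genes
    if a > 0:
        rest = base[a:].sum()
        base[:a] = config.abundant_mass * rest / ((1.0 - config.abundant_mass) * a)
    young = np.tile(base[:, None], (1, K))
    m = config.n_markers_per_type
    for t in range(K):
        block = slice(a + t * m, a + (t + 1) * m)
        young[block, t] *= 2.0 ** config.marker_log2fc
    old = young.copy()
    for g, ct, lfc in config.de_effects:
        if ct is None:
            old[g, :] *= 2.0 ** lfc
        else:
            old[g, ct] *= 2.0 ** lfc
    for g, mrna_lfc, _protein_lfc in config.decoupled_genes:
        old[g, :] *= 2.0 ** mrna_lfc
    return young, old


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float, n: int) -> np.ndarray:
    """n columns of NB counts with mean mu (per gene) and variance mu + alpha mu^2."""
    if alpha < 1e-12:
        lam = np.tile(mu[:, None], (1, n))
    else:
        shape = 1.0 / alpha
        lam = rng.gamma(shape, alpha * mu[:, None], size=(mu.size, n))
    return rng.poisson(lam)


def simulate_celltype_counts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-mouse cell-type counts (mice x types) and per-mouse age labels.

    The lightweight compositional core of :func:`simulate_atlas`, usable on
    its own for proportion-level simulations.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    names = _celltype_names(config.n_celltypes)
    rows, ages, index = [], [], []
    for i in range(config.mice_young + config.mice_old):
        age = "young" if i < config.mice_young else "old"
        comp = np.asarray(config.composition_young if age == "young" else config.composition_old)
        rows.append(rng.multinomial(config.cells_per_mouse, comp))
        ages.append(age)
        index.append(f"m{i:02d}")
    counts = pd.DataFrame(rows, index=index, columns=names)
    return counts, pd.Series(ages, index=index, name="age")


def simulate_atlas(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Draw a droplet count matrix (real cells plus empty droplets).

    Returns the matrix, the per-barcode annotation (with an ``is_cell``
    ground-truth flag; empty droplets carry no cell type), and the
    :class:`SimTruth` record.
    """
    rng = np.random.default_rng(config.seed)
    G, K = config.n_genes, config.n_celltypes
    gene_ids = _gene_ids(G)
    type_names = _celltype_names(K)
    young_w, old_w = _base_profiles(config, rng)
    profiles_young = young_w / young_w.sum(axis=0)
    profiles_old = old_w / old_w.sum(axis=0)

    # ambient pool: library-size-weighted average of cell-type profiles
    n_mice = config.mice_young + config.mice_old
    weights = (
        config.mice_young * np.asarray(config.composition_young)
        + config.mice_old * np.asarray(config.composition_old)
    ) / n_mice
    ambient = profiles_young @ weights
    ambient = ambient / ambient.sum()

    type_counts, mouse_ages = simulate_celltype_counts(config, rng)
    rho = config.ambient_fraction
    mult = np.asarray(config.old_dispersion_multiplier)

    n_cells_total = int(type_counts.to_numpy().sum())
    n_empty_total = config.empty_droplets_per_mouse * n_mice
    dense = np.empty((G, n_cells_total + n_empty_total), dtype=np.int32)
    barcodes: list[str] = []
    mouse_col: list[str] = []
    age_col: list[str] = []
    type_col: list[str] = []
    col = 0
    for mouse in type_counts.index:
        age = mouse_ages[mouse]
        prof = profiles_young if age == "young" else profiles_old
        cell_idx = 0
        for t, tname in enumerate(type_names):
            n = int(type_counts.loc[mouse, tname])
            if n == 0:
                continue
            alpha = config.base_dispersion * (mult[t] if age == "old" else 1.0)
            mu_cell = (1.0 - rho) * config.mean_umi_per_cell * prof[:, t]
            counts = _nb_counts(rng, mu_cell, alpha, n)
            if rho > 0:
                counts += rng.poisson(
                    rho * config.mean_umi_per_cell * ambient[:, None], size=(G, n)
                )
            dense[:, col : col + n] = counts
            col += n
            for _ in range(n):
                barcodes.append(f"{mouse}c{cell_idx:04d}")
                cell_idx += 1
            mouse_col.extend([mouse] * n)
            age_col.extend([age] * n)
            type_col.extend([tname] * n)
    n_cells = len(barcodes)

    empty_barcodes: list[str] = []
    for mouse in type_counts.index:
        n = config.empty_droplets_per_mouse
        totals = rng.poisson(config.mean_umi_per_empty, size=n)
        dense[:, col : col + n] = rng.multinomial(totals, ambient).T
        col += n
        for j in range(n):
            empty_barcodes.append(f"{mouse}e{j:04d}")
        mouse_col.extend([mouse] * n)
        age_col.extend([mouse_ages[mouse]] * n)
    all_barcodes = barcodes + empty_barcodes
    matrix = CountMatrix(sp.csr_matrix(dense), gene_ids, all_barcodes)
    annotation = make_annotation(
        matrix,
        mouse_id=np.array(mouse_col, dtype=object),
        age=np.array(age_col, dtype=object),
        cell_type=np.array(type_col + [pd.NA] * len(empty_barcodes), dtype=object),
    )
    annotation["is_cell"] = np.arange(len(all_barcodes)) < n_cells

    a, m = config.abundant_genes, config.n_markers_per_type
    marker_genes = {
        tname: list(range(a + t * m, a + (t + 1) * m)) for t, tname in enumerate(type_names)
    }
    dispersion = {}
    for t, tname in enumerate(type_names):
        dispersion[(tname, "young")] = config.base_dispersion
        dispersion[(tname, "old")] = config.base_dispersion * mult[t]
    truth = SimTruth(
        gene_ids=gene_ids,
        celltype_names=type_names,
        profiles_young=profiles_young,
        profiles_old=profiles_old,
        ambient_profile=ambient,
        cells=annotation.loc[annotation["is_cell"], ["barcode", "mouse_id", "age", "cell_type"]].reset_index(drop=True),
        empty_barcodes=empty_barcodes,
        dispersion=dispersion,
        marker_genes=marker_genes,
        de_effects=list(config.de_effects),
        decoupled_genes=list(config.decoupled_genes),
        housekeeper_genes=list(config.housekeeper_genes),
        composition_young=np.asarray(config.composition_young),
        composition_old=np.asarray(config.composition_old),
        config=config,
    )
    return matrix, annotation, truth


def simulate_bulk(
    truth: SimTruth,
    config: SimConfig,
    n_replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Whole-organ bulk RNA-seq count table (genes x replicates, both ages).

    Replicate counts are NB draws around the composition-weighted expected
    profile of each age, scaled by log-normal library sizes and a fixed
    per-gene capture bias emulating protocol differences between poly-A
    bulk sequencing and 3' droplet capture.  ``bulk_dispersion == 0`` is the
    noise-free limit (counts equal rounded means).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (downstream DE needs replication)")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    bias = rng.lognormal(0.0, config.bulk_gene_bias_sd, size=len(truth.gene_ids))
    data = {}
    for age in ("young", "old"):
        expected = truth.bulk_expected_profile(age) * bias
        expected = expected / expected.sum()
        for r in range(n_replicates):
            lib = config.bulk_libsize * rng.lognormal(0.0, config.bulk_libsize_log_sd)
            mu = lib * expected
            if config.bulk_dispersion <= 0:
                counts = np.round(mu).astype(np.int64)
            else:
                counts = _nb_counts(rng, mu, config.bulk_dispersion, 1)[:, 0]
            data[f"bulk_{age}_{r + 1}"] = counts
    return pd.DataFrame(data, index=truth.gene_ids)


def _shift_simplex(profile: np.ndarray, shift: float) -> np.ndarray:
    """Move INSOL share down by ``shift``; soluble fractions absorb the mass."""
    out = profile.copy()
    new_insol = float(np.clip(out[3] - shift, 0.02, 0.98))
    soluble = out[:3] * (1.0 - new_insol) / out[:3].sum()
    out[:3] = soluble
    out[3] = new_insol
    return out


def simulate_proteome(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Synthetic QDSP and tissue proteome tables with protein ground truth.

    Protein log2 abundance couples to the pseudobulk transcriptome with
    slope ``protein_coupling`` (plus noise); decoupled genes override the
    age effect with their own protein log2FC.  Each protein carries a
    4-fraction solubility simplex profile; the configured subset gets an
    age-shifted profile at constant total abundance.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    genes = truth.gene_ids
    G = len(genes)
    a = config.protein_coupling
    mrna_young = truth.bulk_expected_profile("young")
    baseline = 20.0 + a * np.log2(mrna_young * 1e6 + 1.0) + rng.normal(0.0, 0.5, size=G)
    protein_lfc = a * truth.bulk_log2fc()
    for g, _mrna_lfc, p_lfc in truth.decoupled_genes:
        protein_lfc[g] = p_lfc

    R, sigma = config.proteome_replicates, config.proteome_sigma
    tissue = {}
    for age in ("young", "old"):
        eff = protein_lfc if age == "old" else 0.0
        for r in range(R):
            tissue[f"{age}_{r + 1}"] = baseline + eff + rng.normal(0.0, sigma, size=G)
    tissue_df = pd.DataFrame(tissue, index=genes)

    profiles_young = rng.dirichlet(np.full(4, 2.0), size=G)
    profiles_old = profiles_young.copy()
    shifted = sorted(set(config.solubility_shifted_genes))
    for g in shifted:
        profiles_old[g] = _shift_simplex(profiles_young[g], config.solubility_shift)

    rows = []
    for age, profs in (("young", profiles_young), ("old", profiles_old)):
        eff = protein_lfc if age == "old" else np.zeros(G)
        for r in range(R):
            noise = rng.normal(0.0, sigma, size=(G, 4))
            values = baseline[:, None] + eff[:, None] + np.log2(profs) + noise
            for fi, fraction in enumerate(FRACTIONS):
                rows.append(
                    pd.DataFrame(
                        {
                            "protein_id": genes,
                            "age": age,
                            "replicate": r + 1,
                            "fraction": fraction,
                            "log2_intensity": values[:, fi],
                        }
                    )
                )
    qdsp = pd.concat(rows, ignore_index=True)
    if config.proteome_missing_rate > 0:
        mask = rng.random(len(qdsp)) < config.proteome_missing_rate
        qdsp.loc[mask, "log2_intensity"] = np.nan

    protein_truth = {
        "protein_log2fc": dict(zip(genes, protein_lfc)),
        "decoupled": {genes[g]: (m, p) for g, m, p in truth.decoupled_genes},
        "solubility_shifted": [genes[g] for g in shifted],
        "profiles_young": profiles_young,
        "profiles_old": profiles_old,
    }
    return qdsp, tissue_df, protein_truth


def truth_to_json(truth: SimTruth) -> dict:
    """JSON-serializable summary of the ground truth (indices, not matrices)."""
    return {
        "gene_count": len(truth.gene_ids),
        "celltype_names": truth.celltype_names,
        "ambient_profile": truth.ambient_profile.tolist(),
        "marker_genes": truth.marker_genes,
        "de_effects": [[g, ct, fc] for g, ct, fc in truth.de_effects],
        "decoupled_genes": [[g, m, p] for g, m, p in truth.decoupled_genes],
        "housekeeper_genes": list(truth.housekeeper_genes),
        "composition_young": truth.composition_young.tolist(),
        "composition_old": truth.composition_old.tolist(),
        "dispersion": {f"{t}|{a}": v for (t, a), v in truth.dispersion.items()},
        "seed": truth.config.seed if truth.config is not None else None,
    }


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)
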