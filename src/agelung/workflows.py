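"""End-to-end study workflows on the synthetic cohorts.

Each function generates the relevant synthetic cohort, runs the analysis
modules on it exactly as a user would, and returns summary numbers with
the generator's ground truth as the yardstick.  These are the canonical
validation runs of the package; tests and the reproduction script both
call them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from . import ambient, atlas, composition, integration, noise, presets, qdsp, sim


def noise_age_tests(seed: int, inflated: bool = True, graded: bool = False,
                    metrics: tuple[str, ...] = ("euclidean",)) -> pd.DataFrame:
    """Per-cell-type noise report for one noise-cohort atlas."""
    cfg = presets.noise_cohort(seed, inflated=inflated, graded=graded)
    matrix, annotation, _ = sim.simulate_atlas(cfg)
    cells = annotation[annotation["is_cell"]]
    cell_matrix = matrix.subset_barcodes(list(cells["barcode"]))
    results = noise.run_noise_pipeline(
        cell_matrix, cells, noise.NoiseConfig(seed=seed), metrics=metrics
    )
    report = results["report"]
    report.insert(0, "atlas_seed", seed)
    return report


def noise_power_summary(n_atlases: int, base_seed: int, inflated: bool) -> pd.DataFrame:
    """Pooled euclidean-metric noise reports over several atlases."""
    return pd.concat(
        [noise_age_tests(base_seed + i, inflated=inflated) for i in range(n_atlases)],
        ignore_index=True,
    )


def noise_metric_agreement(n_atlases: int, base_seed: int) -> dict:
    """Rank correlation of euclidean vs 1-Spearman log2 noise ratios.

    Uses graded dispersion inflation so cell types genuinely differ in
    effect size, and summarizes with the Spearman correlation and a robust
    (Huber) regression slope across cell types.
    """
    import statsmodels.api as sm

    frames = [
        noise_age_tests(base_seed + i, graded=True, metrics=("euclidean", "spearman"))
        for i in range(n_atlases)
    ]
    report = pd.concat(frames, ignore_index=True)
    wide = report.pivot_table(
        index=["atlas_seed", "cell_type"], columns="metric", values="log2_ratio"
    ).dropna()
    rho = float(st.spearmanr(wide["euclidean"], wide["spearman"]).statistic)
    rlm = sm.RLM(
        wide["euclidean"].to_numpy(), sm.add_constant(wide["spearman"].to_numpy())
    ).fit()
    return {"spearman_rho": rho, "robust_slope": float(rlm.params[1]), "n_points": len(wide)}


def ambient_recovery(seed: int) -> dict:
    """Detection precision/recall against the 30-gene ambient truth set,
    plus the housekeeper/restricted partition sizes."""
    cfg = presets.ambient_cohort(seed)
    matrix, annotation, truth = sim.simulate_atlas(cfg)
    cells = annotation[annotation["is_cell"]]
    cell_matrix = matrix.subset_barcodes(list(cells["barcode"]))
    markers = atlas.find_markers(cell_matrix, cells["cell_type"].to_numpy())
    report = ambient.build_ambient_report(matrix, set(cells["barcode"]), markers)
    truth_set = {truth.gene_ids[i] for i in range(cfg.abundant_genes)}
    tp = len(report.ambient_genes & truth_set)
    return {
        "precision": tp / len(report.ambient_genes) if report.ambient_genes else 0.0,
        "recall": tp / len(truth_set),
        "n_ambient": len(report.ambient_genes),
        "n_housekeepers": len(report.housekeepers),
        "n_restricted": len(report.restricted),
        "empty_barcodes": report.empty_barcode_count,
        "mean_empty_umi": report.mean_empty_umi,
    }


def composition_age_p(seed: int, shifted: bool = True) -> float:
    """MDS coordinate-1 age p for one composition-cohort draw."""
    cfg = presets.composition_cohort(seed, shifted=shifted)
    counts, ages = sim.simulate_celltype_counts(cfg)
    props = counts.div(counts.sum(axis=1), axis=0)
    report = composition.mds_age_test(composition.shrink_proportions(props), ages)
    return report.coord1_p


def pseudobulk_recovery(seed: int) -> dict:
    """Pseudobulk conservation and NB-GLM fold-change recovery."""
    cfg = presets.integration_cohort(seed)
    matrix, annotation, truth = sim.simulate_atlas(cfg)
    cells = annotation[annotation["is_cell"]]
    cell_matrix = matrix.subset_barcodes(list(cells["barcode"]))
    pb = integration.pseudobulk(cell_matrix, cells["mouse_id"].to_numpy())
    conserved = int(pb.to_numpy().sum()) == int(cell_matrix.values.sum())
    age = cells.groupby("mouse_id")["age"].first()
    de = integration.nb_differential(pb, age)
    planted = pd.Series(
        {truth.gene_ids[g]: fc for g, ct, fc in truth.de_effects if ct is None}
    )
    expressed = pb.mean(axis=1).reindex(planted.index) >= 20
    err = (de["log2fc"].reindex(planted.index) - planted)[expressed]
    truth_fc = pd.Series(truth.bulk_log2fc(), index=truth.gene_ids)
    big = pb.index[pb.mean(axis=1) >= 20]
    r = st.pearsonr(
        de["log2fc"].reindex(big).dropna(),
        truth_fc[de["log2fc"].reindex(big).dropna().index],
    ).statistic
    return {
        "totals_conserved": conserved,
        "n_planted_expressed": int(expressed.sum()),
        "frac_within_0_3": float((err.abs() <= 0.3).mean()),
        "fc_truth_pearson_r": float(r),
    }


def integration_geometry(seed: int) -> dict:
    """Quantile-normalized three-modality PCA: modality vs age separation."""
    cfg = presets.integration_cohort(seed)
    matrix, annotation, truth = sim.simulate_atlas(cfg)
    cells = annotation[annotation["is_cell"]]
    cell_matrix = matrix.subset_barcodes(list(cells["barcode"]))
    pb = integration.pseudobulk(cell_matrix, cells["mouse_id"].to_numpy())
    mouse_age = cells.groupby("mouse_id")["age"].first()
    bulk = sim.simulate_bulk(truth, cfg, n_replicates=3)
    _, tissue, _ = sim.simulate_proteome(truth, cfg)
    _, scores, evr = integration.merge_modalities(
        integration.log_cpm(pb), integration.log_cpm(bulk), tissue
    )
    age = pd.Series(
        {
            c: (c.split("_")[1] if c.startswith("bulk_") else
                c.split("_")[0] if c.startswith(("young", "old")) else mouse_age[c])
            for c in scores.index
        }
    )
    # nearest-centroid modality accuracy on PCs 1-2
    X = scores[["PC1", "PC2"]].to_numpy()
    labels = scores["modality"].to_numpy()
    centroids = {m: X[labels == m].mean(axis=0) for m in set(labels)}
    assigned = [
        min(centroids, key=lambda m: np.linalg.norm(x - centroids[m])) for x in X
    ]
    accuracy = float(np.mean(np.array(assigned) == labels))
    age_ps = {}
    for pc in ("PC3", "PC4", "PC5"):
        old = scores.loc[(age == "old").to_numpy(), pc]
        young = scores.loc[(age == "young").to_numpy(), pc]
        age_ps[pc] = float(
            st.mannwhitneyu(old, young, alternative="two-sided").pvalue
        )
    return {
        "modality_accuracy_pc12": accuracy,
        "age_p_by_pc": age_ps,
        "best_age_p": min(age_ps.values()),
        "explained_variance": evr[:5].tolist(),
    }


def deconvolution_ranking(seed: int) -> pd.DataFrame:
    """KS marker-signature enrichment of bulk age fold changes.

    The cohort plants a composition increase of the first cell type, so
    its signature should rank first with positive direction.
    """
    cfg = presets.composition_cohort(seed)
    cfg = sim.SimConfig(**{**sim.config_to_dict(cfg), "cells_per_mouse": 300})
    _, _, truth = sim.simulate_atlas(cfg)
    bulk = sim.simulate_bulk(truth, cfg, n_replicates=3)
    age = pd.Series(
        {c: ("young" if "_young_" in c else "old") for c in bulk.columns}
    )
    de = integration.nb_differential(bulk, age)
    marker_sets = {
        ct: [truth.gene_ids[g] for g in genes] for ct, genes in truth.marker_genes.items()
    }
    return integration.ks_signature_enrichment(de["log2fc"], marker_sets)


def qdsp_summary(n_replicates: int, base_seed: int) -> dict:
    """Solubility-ANOVA power and false discovery proportion over cohorts."""
    powers, fdps, max_means = [], [], []
    for i in range(n_replicates):
        cfg = presets.proteome_cohort(base_seed + i)
        _, _, truth = sim.simulate_atlas(cfg)
        qdsp_table, _, protein_truth = sim.simulate_proteome(truth, cfg)
        normalized, _ = qdsp.qdsp_normalize(qdsp_table)
        means = normalized.groupby(["protein_id", "age"])["log2_intensity"].mean()
        max_means.append(float(means.abs().max()))
        result = qdsp.solubility_anova(normalized)
        shifted = set(protein_truth["solubility_shifted"])
        called = set(result.loc[result["significant"].fillna(False), "protein_id"])
        tp = len(called & shifted)
        powers.append(tp / len(shifted))
        fdps.append((len(called) - tp) / max(len(called), 1))
    return {
        "power": float(np.mean(powers)),
        "fdp": float(np.mean(fdps)),
        "max_abs_group_mean": float(np.max(max_means)),
    }
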