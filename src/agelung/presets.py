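"""Canonical synthetic study conditions.

These configs pin down the scenarios the package is validated against:
noise power/calibration cohorts, the ambient-dominant contamination
fixture, the composition-shift cohort, and the multi-omics integration
study.  They are fixed study designs, not tuning knobs — analysis scripts
and tests share them so every consumer sees the same ground truth.
"""

from __future__ import annotations

import numpy as np

from .sim import SimConfig


def noise_cohort(seed: int, inflated: bool = True, graded: bool = False) -> SimConfig:
    """Noise-study cohort: 10 cell types, ~200 cells/type/age, 8+7 mice.

    ``inflated`` doubles the old-age NB dispersion in every cell type;
    ``graded`` spreads the multipliers over [1.25, 3] so cell types differ
    in effect size (used when comparing the two noise metrics).  With
    ``inflated=False`` the generator is null with respect to age.
    """
    if graded:
        mult: float | tuple = tuple(np.linspace(1.25, 3.0, 10))
    elif inflated:
        mult = 2.0
    else:
        mult = 1.0
    uniform = tuple(np.full(10, 0.1))
    return SimConfig(
        n_genes=1000,
        n_celltypes=10,
        cells_per_mouse=286,
        empty_droplets_per_mouse=1,
        old_dispersion_multiplier=mult,
        composition_young=uniform,
        composition_old=uniform,
        seed=seed,
    )


def ambient_cohort(seed: int, ambient_fraction: float = 0.05) -> SimConfig:
    """Ambient-contamination fixture: 30 dominant transcripts feeding the
    ambient pool, ~1,000 empty droplets at ~10 UMIs each.

    The 30 abundant genes (Scgb1a1/Sftpc-like) hold 95% of every cell
    type's transcript mass and therefore dominate the ambient profile;
    they are the detection truth set and double as housekeeper candidates.
    """
    return SimConfig(
        n_genes=1000,
        n_celltypes=10,
        cells_per_mouse=120,
        empty_droplets_per_mouse=67,  # 15 mice -> 1,005 empty droplets
        abundant_genes=30,
        abundant_mass=0.95,
        ambient_fraction=ambient_fraction,
        housekeeper_genes=tuple(range(30)),
        seed=seed,
    )


def composition_cohort(seed: int, shifted: bool = True) -> SimConfig:
    """Composition cohort: 15 mice (8 young / 7 old) at ~1,000 cells per
    mouse, one ciliated-like cell type at 5% in young doubling to ~10% in
    old (the per-mouse cell yield matches the droplet study this design
    emulates)."""
    young = np.full(10, 0.1)
    young[0] = 0.05
    young = young / young.sum()
    if shifted:
        old = young.copy()
        old[0] *= 2.0
        old = old / old.sum()
    else:
        old = young.copy()
    return SimConfig(
        n_genes=500,
        n_celltypes=10,
        cells_per_mouse=988,
        empty_droplets_per_mouse=1,
        composition_young=tuple(young),
        composition_old=tuple(old),
        seed=seed,
    )


def integration_cohort(seed: int, n_de: int = 200, de_log2fc: float = 1.0) -> SimConfig:
    """Multi-omics cohort: global age effects on ``n_de`` genes
    (mass-balanced: half up, half down at ±``de_log2fc``), a composition
    increase of the first cell type, and one mRNA/protein-decoupled gene.

    The balanced effect directions keep the per-cell transcriptome
    normalization from shifting unaffected genes, so planted fold changes
    survive the compositional constraint of droplet counts.
    """
    first_effect = 400  # leave markers (10 types x 10) and a spacer intact
    half = n_de // 2
    de = tuple(
        (first_effect + i, None, de_log2fc if i < half else -de_log2fc) for i in range(n_de)
    )
    decoupled = ((first_effect + n_de + 5, -1.0, 1.0),)
    return SimConfig(
        n_genes=1000,
        n_celltypes=10,
        cells_per_mouse=250,
        empty_droplets_per_mouse=1,
        de_effects=de,
        decoupled_genes=decoupled,
        seed=seed,
    )


def proteome_cohort(seed: int, n_shifted: int = 25) -> SimConfig:
    """Solubility-profiling cohort: ``n_shifted`` proteins whose INSOL
    share drops by 0.35 with age at constant total abundance, 4 replicates
    per age, log2 noise sd 0.25."""
    return SimConfig(
        n_genes=400,
        n_celltypes=4,
        n_markers_per_type=5,
        cells_per_mouse=100,
        empty_droplets_per_mouse=1,
        solubility_shifted_genes=tuple(range(200, 200 + n_shifted)),
        solubility_shift=0.35,
        seed=seed,
    )
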