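# Methods

This note documents the statistical models behind `agelung`, the design
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Generative model

The synthetic cohort mimics a two-age droplet scRNA-seq study with matched
bulk RNA-seq and proteome cohorts.

**Cells.** Each mouse contributes `cells_per_mouse` cells whose types are
multinomial draws from an age-specific composition vector.  A cell of type
*t* at age *a* has expected expression `mean_umi_per_cell × [(1−ρ)·p_t,a +
ρ·q]`, where `p_t,a` is the type's expression profile (a probability vector
over genes), `q` the ambient profile, and ρ (`ambient_fraction`) the
expected ambient fraction.  The cell-derived component is negative binomial
with variance μ + αμ² (gamma–Poisson sampling); the ambient component is
Poisson, reflecting that ambient molecules are a thin Poisson sampling of a
large pool.  Aging inflates α multiplicatively per cell type
(`old_dispersion_multiplier`), which is precisely the data feature the
noise statistics target.

**Profiles.** Gene baseline weights are log-normal (σ =
`baseline_log_sd` = 1.2, a typical expression-abundance spread).  Each cell
type receives a disjoint block of `n_markers_per_type` markers boosted by
2^`marker_log2fc`.  Optionally a leading block of `abundant_genes` genes is
given a fixed joint share (`abundant_mass`) of every type's transcriptome,
emulating the secretory transcripts (club-cell secretoglobin, surfactant
genes) that dominate real lung droplet data and therefore the ambient pool.
Age effects multiply old-age profiles by 2^log2FC either in one cell type
or globally; decoupled genes additionally carry an independent protein
effect.  Because per-cell expected counts are normalized profiles, planted
fold changes are compositional: a large single-direction effect mass shifts
all other genes.  The integration cohort therefore plants mass-balanced
effects (equal numbers up and down), which keeps unaffected genes fixed —
the same reason balanced DE is assumed by median-of-ratios normalization.

**Ambient pool and empty droplets.** The ambient profile is the
library-size-weighted average of cell-type profiles (the pool derives from
lysed cells, so abundant transcripts dominate).  Empty droplets have
Poisson totals with mean `mean_umi_per_empty` (default 10) and multinomial
composition `q`.

**Bulk.** Replicates are NB draws (dispersion `bulk_dispersion` = 0.05, a
typical biological CV for bulk RNA-seq) around the composition-weighted
expected profile of each age, scaled by log-normal library sizes, with a
fixed per-gene log-normal capture bias (`bulk_gene_bias_sd` = 0.4)
representing protocol differences between poly-A bulk libraries and 3'
droplet capture.  Without such a bias the bulk and pseudobulk modalities
would have identical expected profiles and could not exhibit the
modality-level clustering that real multi-platform integrations show.
`bulk_dispersion = 0` is defined as the noise-free limit (counts are
rounded means), giving tests an exactly checkable degenerate case.

**Proteome.** Protein log2 abundance couples to the log pseudobulk
transcriptome with slope `protein_coupling` = 0.6 plus noise — strong but
imperfect mRNA–protein correlation — and age effects propagate through the
same slope unless a gene is decoupled, in which case its protein log2FC is
set directly (opposite-sign decoupling reproduces the basement-membrane
collagen pattern of rising protein despite falling transcript).  Each
protein has a Dirichlet(2,2,2,2) solubility profile over fractions
FR1/FR2/FR3/INSOL; an age-shifted subset moves INSOL mass (default 0.35)
into the soluble fractions at constant total abundance.  Measurement noise
is Gaussian on the log2 scale (σ = 0.25, a routine label-free replicate
CV).

What the generator does **not** emulate: doublets, batch/chemistry
differences between mice, cell-cycle structure, mouse-level random effects
on expression (mice differ only through sampling), UMI saturation, and
protein-level missingness mechanisms beyond missing-at-random.  Passing
tests therefore demonstrate correctness of the statistical machinery under
a faithful but idealized sampling model — not robustness to batch
confounding or structured dropout.

## Pipeline models and conventions

**Cell calling.** Barcodes within the top 1200 by total UMI *and* with
more than 200 genes detected are cells.  Ties at the 1200th total are all
kept, making the rule order-independent and deterministic.

**Consensus HVG.** Per mouse, dispersion z-scores within 20 mean bins
(threshold z > 0.5); consensus keeps genes variable in strictly more than
`min_samples` = 4 mice, then removes cell-cycle genes.  A gene with zero
variance in the normalized data is never called variable, regardless of
binning artifacts.  Selection-by-variability-across-types deliberately
precedes any age comparison so that clustering features are not age-driven.

**Embedding.** Library-size normalization (10⁴ target), log1p, total-UMI
regression, per-gene scaling, then ICA.  ICA's sign and order
indeterminacies are fixed by making each component's largest-magnitude
loading positive and sorting components by source variance; with a fixed
seed the embedding is exactly reproducible.

**Clustering.** Modularity with a resolution parameter on a kNN graph
(k = 15), optimized by the seeded Leiden refinement of the Louvain
objective — chosen over classic Louvain because the available
implementation exposes an explicit seed, making partitions reproducible.
On a disconnected graph the number of communities cannot drop below the
number of components, so the resolution → 0 single-cluster limit applies
to connected graphs.

**Batch silhouette.** Mean silhouette of cells labeled by mouse; 0/0
degeneracies and single-cell mice contribute 0.  Values near zero indicate
the embedding carries no mouse identity.  The QC metric accepts any
embedding dimension; by default it is computed on the clustering embedding
(the upstream analysis it guards), with `k` exposed for a
higher-dimensional variant.

**Markers and cell-type DE.** One-vs-rest (or old-vs-young) two-sided
Wilcoxon rank-sum on log-normalized expression with tie-corrected normal
approximation; exact enumeration is used whenever a test has ≤ 25
observations and no ties.  Fold changes compare group means of normalized
expression with pseudocount ε = 1e-9 (zero/zero → 0).  All-tied inputs are
assigned p = 1.  BH adjustment runs within each label.

**Ambient handling.** Presence fraction across empty-window barcodes
(window [5, 15] total UMIs, threshold 0.25, ≥ 100 barcodes required) is
the detection criterion; with mean-10-UMI droplets this resolves genes
holding ≳ 3% of ambient mass, which is exactly the "abundant transcript"
regime ambient contamination comes from.  Genes absent from the marker
table count as non-specific (conservative: they are masked as
housekeepers).  Masking flags tests rather than correcting counts; the
statistics of unmasked genes are untouched by construction.

**Noise.** Depth equalization is an exact multivariate hypergeometric
downsample to the global minimum total — it absorbs any constant count
rescaling.  Invariant genes are selected per cell type on the equalized
cells (mean bins are quantile cuts over genes sorted by mean with gene-id
tie-breaks; ceil(10% × bin) lowest-CV genes per interior bin, CV ties again
by gene id, guaranteeing determinism and at least one gene per bin).  The
pairwise 1 − Spearman metric uses all genes and also runs on the equalized
matrix by default (`equalize_for_spearman` flag).  Mouse-level ratios
average per-cell distances within mouse; for the pairwise metric only
same-mouse pairs have a well-defined mouse and are used.  "Benjamini"
rather than "Bonferroni" step-up adjustment is used throughout (the BH
procedure is the one consistent with "adjusted p value" usage).

**Composition.** The shrinkage transform y′ = (y(n−1) + 1/K)/n is the
standard compression away from the simplex boundary; it is order-preserving
and row-sum conserving, and distances are computed on the transformed table
(the transform immediately precedes the distance step; a flag exposes raw
distances).  Non-metric (Kruskal) MDS starts from the classical
(Torgerson) solution, 2 components, max 300 iterations, tol 1e-6, falling
back to the classical embedding on failure.  Coordinate 1 is oriented so
the young mean is ≤ the old mean — the test is invariant to sign flips.
The rank-sum test is exact for ≤ 25 mice.

**NB differential expression.** Median-of-ratios size factors enter as
offsets; each gene gets a log-link NB GLM with an age coefficient and a
per-gene dispersion estimated by bounded maximum likelihood (floored at
1e-8, two alternations of GLM fit and dispersion profile).  No
borrowed-strength shrinkage is applied by default: the intended inputs are
pseudobulk/bulk tables where counts are large and per-gene information is
adequate.  Wald p-values, BH adjustment, and a `min_total` = 10 expression
filter complete the table.  An independent DESeq2 fit is used in the test
suite as a cross-check of the fold-change estimates.

**Merging and deconvolution.** Count modalities enter as log2 CPM with a
+0.5 offset.  Quantile normalization is joint across all columns of the
merged matrix (the merged matrix is what gets normalized; per-modality
normalization is exposed as a flag), with ties receiving the average of the
reference values at their tied ranks.  KS signature enrichment reports the
two-sample statistic, a direction (sign of the marker-vs-rest median
difference), and p clamped to [1e-50, 1].  The upstream-regulator score is
the unweighted sign-consistency z with a hypergeometric overlap p; the
dual threshold (|z| > 2 and −log10 p > 7) must both pass for a call.

**QDSP.** Per-protein, per-age mean-centering zeroes the age main effect
exactly — which is why the two-way ANOVA's interaction term is the
informative one: it detects profile *shape* changes.  Sums of squares are
type II (identical to type I/III in the balanced complete design; coherent
under missingness-induced imbalance).  Proteins need ≥ 2 observations in
every (age, fraction) cell; no imputation.  The centering introduces a
weak negative within-group correlation (−σ²/16 for the default 16
observations per age), a second-order effect on the interaction F
confirmed negligible by the null calibration test.  The 2D enrichment
combines dimension p-values by their maximum (conservative) before BH.

## Validation problem sizes

The synthetic study conditions are fixed in `agelung.presets`: noise
cohorts use 10 cell types at ~200 cells/type/age across 8 + 7 mice with
1,000 genes and ~1,500 UMIs/cell (power runs double α in old cells; the
metric-agreement runs grade multipliers over [1.25, 3] so cell types
genuinely differ); the ambient cohort plants 30 dominant transcripts
holding 95% of transcript mass with ~1,000 empty droplets; the composition
cohort uses ~1,000 cells/mouse (the per-mouse yield of the droplet design
it emulates) with one 5% cell type doubling; the integration cohort plants
200 mass-balanced global effects at ±1 log2; the proteome cohort shifts 25
of 400 solubility profiles.  These sizes were chosen once as desk-scale
renditions of the emulated study design.

## Known limitations

* The NB dispersion MLE is noisy at very small replicate numbers; the
  default pipelines apply it to pseudobulk/bulk tables where counts are
  sums over hundreds of cells.
* The pairwise-Spearman noise metric is O(cells²) per group and is meant
  for the equalized group sizes (hundreds of cells), not whole atlases.
* Upstream-regulator scoring implements only the open sign-consistency
  statistic; proprietary weighted causal-network variants are out of scope,
  and networks must be supplied by the user.
* The compositional MDS test detects *that* composition differs with age,
  not *which* cell type moved — by the nature of compositional data the
  per-type deltas are descriptive only.
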