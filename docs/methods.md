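# Methods

`noduleseq` re-implements, as a tested and reusable pipeline, the downstream
statistics of a nodule-transcriptome comparison between legume genotypes with
contrasting biological nitrogen fixation (BNF) efficiency. The pipeline
starts at a gene-level count matrix; read QC, alignment and counting are out
of scope, as are homology searches and structure prediction. This note
documents the models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerically
delicate choices.

## Study design emulated by the generator

The synthetic bundles mirror a two-group design: a high-fixation and a
low-fixation group, each containing four genotypes (two diploid, two
tetraploid) measured in biological triplicate — 24 samples. Defaults of
`GeneratorConfig`:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 20,000 | desk-scale stand-in for a ~40k-gene genome with ~37k genes detected in nodules |
| `de_fraction` | 0.013 | ~1.3% of expressed genes differential (a few hundred DEGs out of tens of thousands) |
| `up_fraction` | 0.75 | observed 3:1 asymmetry of up- vs down-regulated DEGs |
| `de_log2fc_range` | (1.2, 4.0) | planted effects clear the calling threshold of |log2FC| > 1 |
| `nb_dispersion` | 0.05 | typical biological CV ~22% for replicated plant RNA-seq; a mild `+0.25/μ` trend adds shot-noise-like extra dispersion at low counts |
| `library_size_range` | (1e6, 3e6) | log-uniform; smaller than real depths (~19M reads) purely for speed — size-factor recovery is scale-free |
| `dup_mode_proportions` | (.0403, .0991, .0534, .3089, .3275, .1708) | background duplication-mode mix of expressed genes (WGD, tandem, proximal, transposed, dispersed, non-duplicated) |
| `tandem_de_enrichment` | 3 | odds multiplier moving DE genes toward tandem/dispersed modes |
| `diverged_pair_fraction` | 0.75 | ~72–87% of duplicate pairs diverged in expression |
| `pair_latent_sd` / `pair_noise_sd` | 1.0 / 0.1 | conserved pairs share a latent log2 profile; expected pair correlation ≈ 0.98 |
| `n_modules`, `module_size` | 4 × 50 | latent-factor co-expression blocks planted among high-expression genes (baseline log2 level 10.5–12.5, like the leghaemoglobin-dominated top of a nodule transcriptome) so they survive the network stage's occurrence filter |

Counts are negative binomial with log-normal relative abundances, per-genotype
log-normal random effects (σ = 0.07) so replicate clustering has structure,
and planted group fold changes applied to the high-fixation group (low
fixation is the reference throughout). Module genes and duplicate-pair genes
are overwritten with Poisson counts around their latent log2 profiles; the
Poisson noise (≲0.1 log2 units at these expression levels) is part of the
planted noise budget. Traits: ethylene concentration (the acetylene-reduction
proxy of nitrogenase activity, µmol/mL) is gamma-distributed with a
group-dependent shape/scale; fresh mass is affine in ethylene with a steeper
slope for tetraploids plus Gaussian noise.

What the generator does **not** emulate: read-level artifacts, mapping
biases, batch effects, correlated gene-gene background structure beyond the
planted modules and pairs, allele-dosage effects of ploidy, or outlier
samples. Tests passing on these bundles therefore demonstrate correctness of
the statistics under the stated model, not robustness to every real-data
pathology.

All randomness derives from one integer seed; per-purpose streams are keyed
by a SHA-256 digest of the stream name, so bundles are byte-identical across
processes and platforms.

## Normalization and differential expression

Size factors are median-of-ratios: s_j = median over all-positive genes of
count_ij / geometric-mean_i, rescaled to unit geometric mean. QC uses
log2(normalized + 1): pairwise Pearson r, complete-linkage clustering on
d = 1 − r, and PCA of the gene-standardized matrix.

The DE test is a deliberately simple negative-binomial Wald test, not a
re-implementation of any published tool — the scientific content here is the
contrast design and the calling thresholds (|log2FC| > 1, BH-adjusted
p < 0.05, low-count exclusion at raw mean < 2), and acceptance is by error
control and power on synthetic data:

- **Dispersion.** Per-gene method of moments on normalized counts, pooled
  within groups with the shot-noise term removed, clipped to [1e-8, 10];
  then shrunk 50% toward a parametric trend α(μ) = a₀ + a₁/μ fit by least
  squares. The 50/50 shrinkage stabilizes the handful of degrees of freedom
  available at n = 12 without iterative machinery.
- **Effect and SE.** log2FC from group means of normalized counts with a 0.5
  pseudocount; the SE combines the NB variance μ(1/s̄) + αμ² of each group
  mean by the delta method.
- **Reference distribution.** The Wald statistic is referred to a t
  distribution with n₁ + n₂ − 2 degrees of freedom rather than the normal.
  With moment-estimated dispersions at 6–12 samples a normal reference is
  anticonservative; the t correction brings the null rejection rate at 0.05
  to ~0.042–0.046 in simulation (measured in the test suite).
- **Multiplicity.** BH across tested genes only; low-count genes carry no
  p-value and do not enter the family.

The phenotype comparison uses a one-tailed Mann–Whitney U test
(high-fixation > low-fixation), exact when both groups have ≤ 12 tie-free
observations, midrank normal approximation otherwise, plus per-ploidy OLS of
fresh mass on ethylene. Relative qPCR expression is 2^−ΔΔCt with technical
replicates averaged before ΔCt; the calibrator sample's fold is exactly 1.

## NCR peptide scanning

Nodule-specific cysteine-rich (NCR) peptides are short secreted defensin-like
peptides with 4 or 6 conserved cysteines that drive terminal bacteroid
differentiation in indeterminate nodules. The scanner confirms a protein iff
(i) its mature region contains exactly 4 or 6 cysteines with consecutive gaps
inside the spacing grammar, (ii) the precursor is shorter than 150 residues,
and (iii) a signal peptide is present. Every input record receives exactly
one verdict (confirmed / unconfirmed / excluded) with a reason; records
containing X that otherwise pass are left unconfirmed because their
physicochemistry is approximate.

- **Length unit.** The length filter is interpreted as < 150 amino-acid
  residues of the preprotein (the scanned objects are proteins); the
  threshold is a parameter.
- **Spacing grammar.** The default — 4C: C–X(4..12)–C–X(8..30)–C–X(3..12)–C;
  6C inserts two cysteines with X(1..12) gaps — is a configurable default,
  not a reproduction of any published motif; planted ground truth in tests
  is generated from the same grammar, so the tests verify the scanner
  mechanics, not the grammar's biological fidelity.
- **Signal peptide.** A documented heuristic replaces external predictors:
  present iff the first 30 residues contain ≥ 7 consecutive residues with
  mean Kyte–Doolittle hydropathy ≥ 1.6; the cleavage position is the first
  small residue (A/G/S/C/T) after that window within residues 15–35
  (0-based 14–34), else window end + 5. External predictions can be passed
  in as overrides and are then used verbatim.
- **Physicochemistry.** MW from average residue masses minus one water per
  bond; net charge by Henderson–Hasselbalch with EMBOSS-style pKa values
  (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
  Y 10.1); pI by 60-step bisection on [0, 14] (agrees with a 0.001-pH grid
  search within 0.01); GRAVY is mean hydropathy.

## Duplication modes and expression divergence

Per-mode enrichment among DEGs uses a 2×2 two-tailed Fisher exact test
implemented with exact integer arithmetic: the per-table weights
C(r1,k)·C(r2,c1−k) share a common denominator, so the "probability ≤
observed" tie comparison is exact rather than float-tolerant. The odds ratio
is ad/bc with a Haldane 0.5 correction at zero cells. The global comparison
is a chi-squared goodness-of-fit of DEG mode counts against background
proportions (df = 5 for six modes); whether the original analysis was a
goodness-of-fit or a 2×6 contingency test is ambiguous — both give df = 5 —
and the goodness-of-fit form is implemented. The Fisher background defaults
to all expressed classified genes including the DEGs, with an option to
exclude them.

The divergence cutoff is never hard-coded: it is the empirical (type-7,
inclusive) 95% quantile of Pearson correlations over 10,000 gene pairs drawn
uniformly without replacement from all non-constant expressed genes, on
log2(normalized + 1) profiles (raw counts would let library size dominate
the correlation). Real nodule data carry correlation structure that pushes
this cutoff well above the independence null (realizations around r ≈ 0.67
occur at ~23 samples); the value is dataset-specific and always recomputed,
never assumed. Pairs with r below
the cutoff are diverged; pairs with a constant profile are undefined; when a
DE table is supplied only pairs with ≥ 1 differentially expressed member are
classified.

## Co-expression modules

The module stage is a simplified signed-hybrid workflow:

1. **Transform and filter.** log2(normalized + 1) — a documented stand-in
   for a variance-stabilizing transform sharing its scale — then keep genes
   with transformed value ≥ 10 in ≥ 3 samples.
2. **Adjacency.** a_ij = cor(i,j)^β for positive correlations, 0 otherwise
   (signed hybrid), β = 6; constant profiles get zero rows with a warning.
3. **TOM.** TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij);
   dissimilarity 1 − TOM.
4. **Detection.** Average-linkage clustering; initial clusters from a static
   cut at absolute dendrogram height 0.99. A cut at a *quantile* of merge
   heights was tried first and rejected: with moderate gene counts the top
   percentile of merges is a single merge, collapsing everything into one
   cluster, whereas unrelated genes merge at heights just below 1, so an
   absolute near-1 cut isolates coherent branches. Dynamic branch-cutting
   sensitivity (deepSplit) is not replicated; the contract is module
   recovery on planted truth. Clusters below `min_module_size` (20) fall to
   "grey"; modules whose eigengene dissimilarity 1 − cor is below
   `merge_cut_height` (0.45) merge iteratively; final labels are color names
   by decreasing size.
5. **Eigengenes.** First right singular vector of the gene-standardized
   module submatrix, unit norm, sign-oriented to correlate positively with
   the module mean profile; variance explained is s₁²/Σs².
6. **Traits.** Pearson r and two-sided p per module × trait, flagged at
   p < 0.01; fixation class and ploidy coded 0/1, genotypes one-hot.
7. **Enrichment.** Upper-tail hypergeometric p per term with BH FDR within
   each module, enriched at FDR < 0.05. The universe is the post-filter
   gene set — the population actually tested.

The edge-list export takes a free adjacency threshold; note that an
"adjacency threshold = 2" cannot be an adjacency value (adjacency ≤ 1), so
no default is claimed for it.

## Pipeline and reproducibility

`pipeline run --config F` executes simulate → de → ncr → dup-diverge →
modules in order, writing each stage's outputs before the next starts and a
JSON run report with per-stage input hashes, parameters, row counts and
captured warnings. All stage seeds derive from the single top-level seed via
SHA-256 of the stage name, so re-running one stage from persisted
intermediates reproduces the full-run output byte for byte (tested).

## Problem sizes used in the test and acceptance runs

Simulation-based checks run at desk scale, chosen as the package's own test
design: null DE calibration on 5,000-gene 2×6 bundles; power/FDR on
4,000-gene 2×12 bundles with planted |log2FC| = 2 over 5 seeds; divergence
recovery on 1,200-gene bundles with 120 pairs over 10 seeds; tandem
enrichment power on 100 catalogs of 20,000 genes; module recovery on
two-block matrices (2 × 30 genes + 40 background, 20 samples) over 10 seeds;
Fisher exactness over the symmetry-reduced set of all 2×2 tables with
margins ≤ 30. `scripts/acceptance.py` runs the full bundle at the
generator's defaults (20,000 genes, 24 samples).

## Known limitations

- The DE test is not exchangeable with any specific published NB framework
  (no independent filtering, no outlier handling, single-factor design;
  ploidy is a stratification label, not a covariate).
- The log transform is not a true variance-stabilizing transform; filter
  membership and module structure are the contract, not transformed values.
- The signal-peptide heuristic is a hydropathy rule, not a trained
  predictor; treat its calls as screening, not evidence.
- The static-cut module detector will split long gradient-like branches
  differently than dynamic tree cutting; module counts are not comparable
  across implementations.
- Empirical quantities printed by any one study (number of DEGs, a specific
  divergence cutoff, a specific module count) are realizations on that
  study's data and are not reproduction targets for synthetic bundles.
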