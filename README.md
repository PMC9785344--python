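# noduleseq

Analysis toolkit for root-nodule transcriptomes of legumes with contrasting
**biological nitrogen fixation (BNF)** efficiency. Legumes such as red clover
house rhizobia in root nodules, where nitrogenase reduces atmospheric N₂ to
ammonium; fixation efficiency varies strongly between genotypes, and bulk
RNA-seq of nodules from high- vs low-fixing genotypes is a standard way to
find the genes behind that variation. `noduleseq` implements the downstream
statistics of such a study as a tested, seeded, reusable pipeline:

- **Differential expression** between BNF classes: median-of-ratios size
  factors, replicate QC (Pearson r, complete-linkage clustering on d = 1 − r,
  PCA), and a negative-binomial Wald test with trended dispersion shrinkage.
  A gene is a DEG iff |log₂FC| > 1 and BH-adjusted p < 0.05; genes with raw
  mean count < 2 are excluded as low counts.
- **NCR peptide scanning**: nodule-specific cysteine-rich peptides are short
  (< 150 aa) secreted defensin-like peptides with 4 or 6 conserved cysteines
  that drive bacteroid differentiation in indeterminate nodules. The scanner
  checks cysteine architecture, length, and a hydropathy-based signal-peptide
  heuristic, and computes MW, pI, net charge, and GRAVY.
- **Gene-duplication analysis**: per-mode enrichment of DEGs (WGD, tandem,
  proximal, transposed, dispersed, non-duplicated) via exact-integer
  two-tailed Fisher tests plus a global χ² goodness-of-fit; duplicate-pair
  expression divergence called against a resampled null — the 95% quantile
  of Pearson r over 10,000 random gene pairs (r* recomputed from data, never
  hard-coded).
- **Co-expression modules**: signed-hybrid adjacency (cor⁺)^β with β = 6,
  topological overlap, average-linkage clustering with a static cut,
  min module size 20, eigengene merging at height 0.45, module eigengenes,
  module–trait correlation (flagged at p < 0.01), and hypergeometric term
  enrichment with BH FDR < 0.05.
- **Synthetic data generator**: seeded experiment bundles (counts, traits,
  duplication catalog, duplicate pairs, proteins, annotation, qPCR Ct table)
  with planted ground truth for every downstream stage, emulating a
  2-group × 4-genotype × 3-replicate design.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

Generate a bundle and run everything with one config:

```bash
noduleseq simulate --seed 17 --outdir bundle
noduleseq de --counts bundle/counts.tsv --samples bundle/samples.tsv --out results
noduleseq dup-diverge --catalog bundle/dup_catalog.tsv --pairs bundle/dup_pairs.tsv \
    --counts bundle/counts.tsv --samples bundle/samples.tsv \
    --de-results results/de_results.tsv --seed 17 --out results
noduleseq ncr-scan --fasta bundle/proteins.fasta --de-results results/de_results.tsv --out results
noduleseq modules --counts bundle/counts.tsv --samples bundle/samples.tsv \
    --annotation bundle/annotation.tsv --out results
```

or in Python, against planted truth:

```python
from noduleseq import *

cfg = GeneratorConfig(seed=313914839)            # derived from --seed 1
counts, samples, truth = generate_counts(cfg)
factors = compute_size_factors(counts)
de = test_differential_expression(counts, factors, samples)
de["status"].value_counts()
# not_de 19640, de_up 195, low_count 102, de_down 63
```

The full acceptance run at `--seed 1` (same bundle, after duplicate pairs
and the qPCR reference gene are planted into the matrix) prints:

- `de_genes_called = 264` of 20,000 genes, `74.2%` up-regulated in the
  high-BNF group — the generator plants ~1.3% DEGs with a 3:1 up:down split,
  and the caller recovers them at recall 0.992 with empirical FDR 0.008.
- `null_correlation_cutoff = 0.354` — the 95% null quantile of pair
  correlations at 24 samples; duplicate pairs with r below it are "diverged"
  (95.5% of planted pair labels recovered; 67% of pairs diverged).
- `ncr_confirmed = 33` of 153 scanned proteins, `4` of them differentially
  expressed — all 33 planted NCR-like peptides found, zero decoys confirmed.
- `modules_detected = 5` with planted-block recovery ARI 1.0 and eigengene ↔
  latent-factor correlation 0.999; the top fixation-trait correlation of a
  module eigengene is |r| = 0.998.
- The printed duplication-mode worked example gives χ² = 23.81 (df 5,
  p = 2.4 × 10⁻⁴) with tandem (p = 0.0012), dispersed (p = 0.0498) and
  non-duplicated (p = 0.0009) modes significant per-mode at α = 0.05.

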