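"""Seeded synthetic experiment bundles with planted ground truth.

The generator emulates the statistical structure of a nodule RNA-seq study of
biological nitrogen fixation (BNF) efficiency: two contrasting genotype groups
(high vs low fixation), each with diploid and tetraploid genotypes measured in
biological triplicate; negative-binomial counts with planted differentially
expressed genes; a gene-duplication catalog with planted tandem/dispersed
over-representation among DE genes; duplicate pairs with planted conserved vs
diverged co-expression; latent-factor co-expression modules with enriched
annotation terms; NCR-like peptides plus single-violation decoys; and a qPCR
Ct table tied to the count matrix.

Everything is driven by a single integer seed; identical configurations and
seeds yield byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigurationError, ConsistencyError, InputError

DUPLICATION_MODES = ("WGD", "TD", "PD", "RD", "DSD", "ND")

#: Background duplication-mode proportions of genes expressed in nodules
#: (WGD, tandem, proximal, transposed, dispersed, non-duplicated).
DEFAULT_MODE_PROPORTIONS = (0.0403, 0.0991, 0.0534, 0.3089, 0.3275, 0.1708)

_HYDROPHOBIC = "LIVF"  # signal-peptide core residues (no A: A is a cleavage residue)
_FILLER = "KRNDEQHPW"  # hydrophilic, non-cysteine, non-small filler
_SMALL = "AGSCT"  # small residues accepted at the cleavage site


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic experiment.

    Defaults mirror the emulated study design: 8 genotypes (4 per BNF group,
    half diploid, half tetraploid) x 3 replicates, ~1.3% of genes DE with a
    3:1 up:down split, background duplication-mode proportions from the
    expressed-gene column of the study's mode table, tandem/dispersed DE
    enrichment odds of 3, and 75% of duplicate pairs diverged in expression.
    """

    n_genes: int = 20000
    n_genotypes_per_group: int = 4
    n_replicates: int = 3
    de_fraction: float = 0.013
    de_log2fc_range: tuple[float, float] = (1.2, 4.0)
    up_fraction: float = 0.75
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (1.0e6, 3.0e6)
    dup_mode_proportions: tuple[float, ...] = DEFAULT_MODE_PROPORTIONS
    tandem_de_enrichment: float = 3.0
    n_duplicate_pairs: int = 400
    diverged_pair_fraction: float = 0.75
    pair_latent_sd: float = 1.0
    pair_noise_sd: float = 0.1
    n_modules: int = 4
    module_size: int = 50
    module_noise_sd: float = 0.3
    n_background_terms: int = 15
    ncr_count: int = 33
    decoy_count: int = 120
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_genotypes_per_group < 1:
            raise ConfigurationError("n_genotypes_per_group must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ConfigurationError("up_fraction must lie in [0, 1]")
        if not 0.0 <= self.diverged_pair_fraction <= 1.0:
            raise ConfigurationError("diverged_pair_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.de_log2fc_range[0] > self.de_log2fc_range[1]:
            raise ConfigurationError("de_log2fc_range must be ordered (lo, hi)")
        if self.library_size_range[0] <= 0 or self.library_size_range[0] > self.library_size_range[1]:
            raise ConfigurationError("library_size_range must be positive and ordered")
        props = np.asarray(self.dup_mode_proportions, dtype=float)
        if props.shape != (6,):
            raise ConfigurationError("dup_mode_proportions must have 6 entries (WGD, TD, PD, RD, DSD, ND)")
        if (props < 0).any() or (props > 1).any():
            raise ConfigurationError("dup_mode_proportions entries must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError("dup_mode_proportions must sum to 1 within 1e-12")
        if self.tandem_de_enrichment < 1:
            raise ConfigurationError("tandem_de_enrichment must be >= 1")
        if self.ncr_count < 0 or self.decoy_count < 0:
            raise ConfigurationError("ncr_count and decoy_count must be >= 0")


@dataclass
class GroundTruth:
    """Sidecar record of everything the generator planted."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> true log2FC
    pair_divergence: dict[str, str] = field(default_factory=dict)  # "g1|g2" -> conserved/diverged
    true_modules: dict[str, int] = field(default_factory=dict)  # gene -> latent factor id
    module_latents: dict[int, list[float]] = field(default_factory=dict)  # factor id -> per-sample latent
    ncr_ids: list[str] = field(default_factory=list)
    decoy_reasons: dict[str, str] = field(default_factory=dict)  # seq id -> violated criterion
    planted_terms: dict[str, int] = field(default_factory=dict)  # term -> enriched module id
    ct_reference: str | None = None
    ct_calibrator: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        gt = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        gt.true_modules = {g: int(m) for g, m in gt.true_modules.items()}
        gt.module_latents = {int(m): v for m, v in gt.module_latents.items()}
        gt.planted_terms = {t: int(m) for t, m in gt.planted_terms.items()}
        return gt


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    """Independent per-stream generator derived from the config seed.

    Streams are keyed by a stable digest of the stream name so bundles are
    reproducible across processes.
    """
    import hashlib

    key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little") & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), key)))


def generate_counts(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the count matrix, sample metadata (with traits), and ground truth.

    Counts are negative binomial with log-normal baseline abundances, a mild
    1/mean dispersion trend, log-uniform library sizes, small log-normal
    genotype effects, and planted group fold changes for DE genes. Module
    genes are overwritten with Poisson counts around shared latent factors so
    co-expression module detection has recoverable structure.
    """
    config.validate()
    rng = _rng(config, "counts")
    n = config.n_genes
    truth = GroundTruth()

    gene_ids = [f"gene{i:05d}" for i in range(n)]

    # -- design ---------------------------------------------------------------
    groups, genotypes, ploidies, reps = [], [], [], []
    for grp in ("high", "low"):
        for g in range(config.n_genotypes_per_group):
            geno = f"{grp[0].upper()}{g + 1}"
            ploidy = "2n" if g < (config.n_genotypes_per_group + 1) // 2 else "4n"
            for r in range(config.n_replicates):
                groups.append(grp)
                genotypes.append(geno)
                ploidies.append(ploidy)
                reps.append(r + 1)
    sample_ids = [f"{g}_r{r}" for g, r in zip(genotypes, reps)]
    n_samples = len(sample_ids)
    is_high = np.array([g == "high" for g in groups])

    # -- per-gene parameters --------------------------------------------------
    rel = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    rel /= rel.sum()
    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    lib_med = np.median(lib)

    mu_base = rel * lib_med  # expected counts at the median library size
    disp = config.nb_dispersion + 0.25 / np.maximum(mu_base, 0.1)  # mild mean-dispersion trend
    disp = np.minimum(disp, 5.0)

    # -- planted DE genes -----------------------------------------------------
    n_de = int(np.floor(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    lfc = np.zeros(n)
    if n_de:
        mags = rng.uniform(config.de_log2fc_range[0], config.de_log2fc_range[1], size=n_de)
        n_up = int(round(config.up_fraction * n_de))
        signs = np.ones(n_de)
        signs[n_up:] = -1.0
        lfc[de_idx] = mags * signs
        truth.de_genes = {gene_ids[i]: float(lfc[i]) for i in de_idx}

    # -- genotype random effects ----------------------------------------------
    geno_names = sorted(set(genotypes))
    geno_eff = rng.lognormal(mean=0.0, sigma=0.07, size=(n, len(geno_names)))
    geno_col = np.array([geno_names.index(g) for g in genotypes])

    # -- mean matrix and NB draw ----------------------------------------------
    mu = (
        mu_base[:, None]
        * (lib / lib_med)[None, :]
        * geno_eff[:, geno_col]
        * np.exp2(lfc[:, None] * is_high[None, :])
    )
    mu = np.maximum(mu, 1e-8)
    p_nb = 1.0 / (1.0 + disp[:, None] * mu)
    counts = rng.negative_binomial(1.0 / disp[:, None], p_nb)

    # -- planted co-expression modules ----------------------------------------
    if config.n_modules > 0 and config.module_size > 0:
        pool = np.setdiff1d(np.arange(n), de_idx)
        need = config.n_modules * config.module_size
        if need > pool.size:
            raise ConfigurationError("n_modules * module_size exceeds the non-DE gene pool")
        chosen = rng.choice(pool, size=need, replace=False)
        for m in range(config.n_modules):
            members = chosen[m * config.module_size : (m + 1) * config.module_size]
            latent = rng.normal(0.0, 1.0, size=n_samples)
            truth.module_latents[m] = [float(v) for v in latent]
            # high-expression modules (like the leghaemoglobin-dominated profiles of
            # nodules) so the planted structure survives the network stage's
            # occurrence filter on transformed counts
            base = rng.uniform(10.5, 12.5)
            loading = rng.uniform(0.8, 1.2, size=members.size)
            log2_mu = (
                base
                + loading[:, None] * latent[None, :]
                + rng.normal(0.0, config.module_noise_sd, size=(members.size, n_samples))
                + np.log2(lib / lib_med)[None, :]
            )
            counts[members, :] = rng.poisson(np.exp2(log2_mu))
            for i in members:
                truth.true_modules[gene_ids[i]] = m

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)

    # -- traits: ethylene (ARA proxy) and fresh mass --------------------------
    trng = _rng(config, "traits")
    ethylene = np.where(
        is_high,
        trng.gamma(shape=6.0, scale=0.30, size=n_samples),
        trng.gamma(shape=2.0, scale=0.20, size=n_samples),
    )
    slope = np.where(np.array(ploidies) == "4n", 450.0, 250.0)  # mass response steeper in 4n
    mass = 150.0 + slope * ethylene + trng.normal(0.0, 25.0, size=n_samples)
    mass = np.maximum(mass, 10.0)

    samples_df = pd.DataFrame(
        {
            "genotype": genotypes,
            "replicate": reps,
            "bnf_class": groups,
            "ploidy": ploidies,
            "fresh_mass": np.round(mass, 2),
            "ethylene": np.round(ethylene, 5),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return counts_df, samples_df, truth


def assign_duplication_modes(
    rng: np.random.Generator,
    n_genes: int,
    proportions: np.ndarray,
    de_mask: np.ndarray,
    tandem_de_enrichment: float,
) -> np.ndarray:
    """Draw per-gene duplication-mode labels.

    Background genes follow ``proportions``; DE genes are drawn from the same
    proportions reweighted by ``tandem_de_enrichment`` odds on the tandem (TD)
    and dispersed (DSD) categories, emulating over-representation of those
    modes among differentially expressed genes.
    """
    proportions = np.asarray(proportions, dtype=float)
    modes = np.array(DUPLICATION_MODES)
    labels = rng.choice(modes, size=n_genes, p=proportions)
    if de_mask.any() and tandem_de_enrichment != 1.0:
        w = proportions.copy()
        w[list(DUPLICATION_MODES).index("TD")] *= tandem_de_enrichment
        w[list(DUPLICATION_MODES).index("DSD")] *= tandem_de_enrichment
        w /= w.sum()
        labels[de_mask] = rng.choice(modes, size=int(de_mask.sum()), p=w)
    return labels


def generate_duplication_catalog(
    config: GeneratorConfig,
    truth: GroundTruth,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign duplication modes and build duplicate pairs with planted correlation.

    Mutates ``counts`` in place for pair-member genes: conserved pairs share a
    per-sample latent log2 profile (noise sd ``pair_noise_sd``; expected r near
    1), diverged pairs get independent latents (expected r near 0). Pairs
    containing planted DE genes keep a group shift on the latent scale, with a
    conserved pair sharing one fold change (truth is updated accordingly).
    """
    config.validate()
    unknown = set(truth.de_genes) - set(counts.index)
    if unknown:
        raise ConsistencyError(f"truth names genes absent from the count matrix: {sorted(unknown)[:5]}")
    rng = _rng(config, "duplication")
    gene_ids = list(counts.index)
    de_mask = np.array([g in truth.de_genes for g in gene_ids])
    labels = assign_duplication_modes(
        rng, len(gene_ids), np.asarray(config.dup_mode_proportions), de_mask, config.tandem_de_enrichment
    )
    catalog = pd.Series(labels, index=counts.index, name="mode")

    # Pair pool: duplicated genes not already carrying module or reference structure.
    reserved = set(truth.true_modules) | ({truth.ct_reference} if truth.ct_reference else set())
    lib_factor = counts.sum(axis=0).to_numpy(dtype=float)
    lib_factor = lib_factor / np.median(lib_factor)
    is_high = (samples.loc[counts.columns, "bnf_class"] == "high").to_numpy()

    pairs: list[tuple[str, str, str]] = []
    per_mode_pool = {
        m: [g for g in gene_ids if catalog[g] == m and g not in reserved] for m in DUPLICATION_MODES if m != "ND"
    }
    for m in per_mode_pool:
        rng.shuffle(per_mode_pool[m])
    mode_cycle = [m for m in DUPLICATION_MODES if m != "ND"]
    mi = 0
    while len(pairs) < config.n_duplicate_pairs and any(len(v) >= 2 for v in per_mode_pool.values()):
        m = mode_cycle[mi % len(mode_cycle)]
        mi += 1
        pool = per_mode_pool[m]
        if len(pool) < 2:
            continue
        g1, g2 = pool.pop(), pool.pop()
        pairs.append((g1, g2, m))

    n_pairs = len(pairs)
    diverged = rng.random(n_pairs) < config.diverged_pair_fraction
    cmat = counts.to_numpy()
    index_of = {g: i for i, g in enumerate(gene_ids)}
    n_samples = counts.shape[1]
    for (g1, g2, _m), div in zip(pairs, diverged):
        base = rng.uniform(6.0, 9.0)
        lfc1 = truth.de_genes.get(g1, 0.0)
        lfc2 = truth.de_genes.get(g2, 0.0)
        if not div:
            # conserved: one latent, one shared fold change
            shared_lfc = lfc1 if lfc1 != 0.0 else lfc2
            if shared_lfc != 0.0:
                for g in (g1, g2):
                    truth.de_genes[g] = float(shared_lfc)
            latent = base + rng.normal(0.0, config.pair_latent_sd, size=n_samples)
            latent = latent + shared_lfc * is_high
            profiles = [latent + rng.normal(0.0, config.pair_noise_sd, size=n_samples) for _ in range(2)]
        else:
            profiles = []
            for lfc_g in (lfc1, lfc2):
                latent = base + rng.normal(0.0, config.pair_latent_sd, size=n_samples)
                profiles.append(
                    latent + lfc_g * is_high + rng.normal(0.0, config.pair_noise_sd, size=n_samples)
                )
        for g, prof in zip((g1, g2), profiles):
            cmat[index_of[g], :] = rng.poisson(np.exp2(prof) * lib_factor)
        truth.pair_divergence[f"{g1}|{g2}"] = "diverged" if div else "conserved"
    counts.iloc[:, :] = cmat

    pairs_df = pd.DataFrame(pairs, columns=["gene1", "gene2", "mode"])
    return catalog, pairs_df


def generate_annotation(config: GeneratorConfig, truth: GroundTruth, counts: pd.DataFrame) -> pd.DataFrame:
    """Gene -> term annotation with one planted enriched term per module.

    Each planted term covers 80% of its module's genes plus ~5% of a random
    background draw; additional background terms annotate random gene sets.
    """
    rng = _rng(config, "annotation")
    gene_ids = np.array(counts.index)
    rows: list[tuple[str, str]] = []
    module_ids = sorted(set(truth.true_modules.values()))
    for m in module_ids:
        term = f"TERM:{m:04d}"
        members = np.array([g for g, mm in truth.true_modules.items() if mm == m])
        n_in = max(1, int(round(0.8 * members.size)))
        for g in rng.choice(members, size=n_in, replace=False):
            rows.append((g, term))
        bg = rng.choice(gene_ids, size=max(1, int(0.05 * min(gene_ids.size, 400))), replace=False)
        for g in bg:
            rows.append((g, term))
        truth.planted_terms[term] = m
    for t in range(config.n_background_terms):
        term = f"TERM:BG{t:03d}"
        size = int(rng.integers(10, 60))
        for g in rng.choice(gene_ids, size=min(size, gene_ids.size), replace=False):
            rows.append((g, term))
    df = pd.DataFrame(rows, columns=["gene_id", "term_id"]).drop_duplicates()
    return df.sort_values(["term_id", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Protein generation


def _signal_prefix(rng: np.random.Generator, with_stretch: bool = True) -> str:
    """N-terminal signal peptide: Met, hydrophobic stretch, filler, cleavage residue.

    The cleavage residue (G) sits at 0-based index >= 15 so the scanner's
    default cleavage search window (residues 15..35, 0-based 14..34) finds it.
    """
    n_h = int(rng.integers(10, 15))
    if with_stretch:
        stretch = "".join(rng.choice(list(_HYDROPHOBIC), size=n_h))
    else:
        stretch = "".join(rng.choice(list(_FILLER), size=n_h))
    prefix = "M" + stretch
    while len(prefix) < 16:
        prefix += str(rng.choice(list(_FILLER)))
    return prefix + "G"  # cleavage site at the final G


def _mature_region(rng: np.random.Generator, n_cys: int, bounds: list[tuple[int, int]]) -> str:
    gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in bounds]
    lead = "".join(rng.choice(list(_FILLER), size=int(rng.integers(2, 6))))
    body = "C"
    for gap in gaps:
        body += "".join(rng.choice(list(_FILLER), size=gap)) + "C"
    tail = "".join(rng.choice(list(_FILLER), size=int(rng.integers(2, 8))))
    return lead + body + tail


def generate_proteins(
    config: GeneratorConfig,
    truth: GroundTruth | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Planted NCR-like peptides plus decoys that each violate exactly one criterion.

    Planted records have a hydrophobic signal stretch, < 150 residues, and 4
    or 6 mature-region cysteines spaced inside the scanner's default grammar.
    Decoy violations cycle through: length >= 150, wrong cysteine count,
    spacing out of bounds, missing signal stretch; the violated criterion is
    recorded in the ground truth.

    If ``gene_ids`` is given, sequence ids are drawn from it (DE genes first
    when ``truth`` carries any) so candidates can be joined with DE results.
    """
    from .ncr import PATTERN_4C, PATTERN_6C  # default grammar shared with the scanner

    config.validate()
    if truth is None:
        truth = GroundTruth()
    rng = _rng(config, "proteins")

    ids: list[str]
    total = config.ncr_count + config.decoy_count
    if gene_ids is not None:
        if total > len(gene_ids):
            raise ConfigurationError("ncr_count + decoy_count exceeds available gene ids")
        de_first = [g for g in gene_ids if g in truth.de_genes][:4]
        rest = [g for g in gene_ids if g not in de_first]
        order = np.array(rest)
        rng.shuffle(order)
        ids = (de_first + list(order))[:total]
    else:
        ids = [f"seq{i:04d}" for i in range(total)]

    records: list[tuple[str, str]] = []
    patterns = [PATTERN_4C, PATTERN_6C]
    for i in range(config.ncr_count):
        pat = patterns[i % 2]
        seq = _signal_prefix(rng) + _mature_region(rng, pat.n_cys, pat.spacing_bounds)
        assert len(seq) < 150
        records.append((ids[i], seq))
        truth.ncr_ids.append(ids[i])

    violations = ["length", "cysteine count", "spacing", "signal peptide"]
    for j in range(config.decoy_count):
        kind = violations[j % 4]
        pat = patterns[j % 2]
        sid = ids[config.ncr_count + j]
        if kind == "length":
            seq = _signal_prefix(rng) + _mature_region(rng, pat.n_cys, pat.spacing_bounds)
            pad = 150 - len(seq) + int(rng.integers(1, 20))
            seq += "".join(rng.choice(list(_FILLER), size=pad))
        elif kind == "cysteine count":
            bad_n = int(rng.choice([3, 5, 7]))
            bounds = [(1, 12)] * (bad_n - 1)
            seq = _signal_prefix(rng) + _mature_region(rng, bad_n, bounds)
        elif kind == "spacing":
            bounds = list(pat.spacing_bounds)
            k = int(rng.integers(0, len(bounds)))
            bounds[k] = (bounds[k][1] + 5, bounds[k][1] + 10)  # push one gap above its bound
            seq = _signal_prefix(rng) + _mature_region(rng, pat.n_cys, bounds)
        else:  # no hydrophobic signal stretch
            seq = _signal_prefix(rng, with_stretch=False) + _mature_region(rng, pat.n_cys, pat.spacing_bounds)
        records.append((sid, seq))
        truth.decoy_reasons[sid] = kind
    return records, truth


def generate_ct_table(
    truth: GroundTruth,
    counts: pd.DataFrame,
    config: GeneratorConfig,
    n_target_genes: int = 8,
    n_tech_replicates: int = 3,
) -> pd.DataFrame:
    """qPCR Ct table tied to the count matrix.

    Designates (and overwrites) a reference gene with uniform normalized
    expression, then emits Ct values that decrease by one cycle per doubling
    of normalized expression, in technical triplicate with small noise.
    """
    rng = _rng(config, "ct")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    lib_factor = lib / np.median(lib)

    # reference gene: constant normalized expression across samples
    pair_members = {g for key in truth.pair_divergence for g in key.split("|")}
    candidates = [
        g
        for g in counts.index
        if g not in truth.de_genes and g not in truth.true_modules and g not in pair_members
    ]
    if not candidates:
        raise InputError("no gene available to serve as the uniform reference")
    ref = candidates[0]
    counts.loc[ref] = np.round(500.0 * lib_factor).astype(int)
    truth.ct_reference = ref

    de_targets = [g for g in truth.de_genes if g != ref][: n_target_genes // 2]
    others = [g for g in counts.index if g != ref and g not in de_targets]
    extra = list(rng.choice(others, size=max(0, n_target_genes - len(de_targets)), replace=False))
    targets = de_targets + extra

    rows = []
    for gene in [ref] + targets:
        q = counts.loc[gene].to_numpy(dtype=float) / lib_factor
        ct0 = 35.0 - np.log2(q + 1.0)
        for rep in range(1, n_tech_replicates + 1):
            noisy = ct0 + rng.normal(0.0, 0.05, size=ct0.size)
            for sample, ct in zip(counts.columns, noisy):
                rows.append((sample, gene, rep, round(float(ct), 4)))
    df = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    # calibrator: sample where the first target is least expressed (highest mean Ct)
    if targets:
        first = df[df["gene"] == targets[0]].groupby("sample")["ct"].mean()
        truth.ct_calibrator = str(first.idxmax())
    return df


def generate_bundle(config: GeneratorConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write a complete experiment bundle to ``outdir``.

    Files: counts.tsv, samples.tsv, proteins.fasta, dup_catalog.tsv,
    dup_pairs.tsv, annotation.tsv, ct.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, samples, truth = generate_counts(config)
    catalog, pairs = generate_duplication_catalog(config, truth, counts, samples)
    annotation = generate_annotation(config, truth, counts)
    ct = generate_ct_table(truth, counts, config)
    proteins, truth = generate_proteins(config, truth, gene_ids=list(counts.index))

    io.write_counts(counts, outdir / "counts.tsv")
    io.write_samples(samples, outdir / "samples.tsv")
    io.write_fasta(proteins, outdir / "proteins.fasta")
    catalog.rename("mode").to_frame().to_csv(outdir / "dup_catalog.tsv", sep="\t", index_label="gene_id")
    pairs.to_csv(outdir / "dup_pairs.tsv", sep="\t", index=False)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    io.write_json(truth.to_dict(), outdir / "truth.json")
    return truth
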