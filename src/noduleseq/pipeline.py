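"""End-to-end pipeline orchestration with a single YAML config.

Stages run in dependency order (simulate -> de -> ncr -> dup-diverge ->
modules -> enrich); each stage's outputs are written before the next starts
and a machine-readable run report collects per-stage input hashes,
parameters, row counts, and warnings. All randomness flows from one
top-level seed via per-stage derived seeds, so any stage re-run in isolation
reproduces its slice of the full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import duplication, expression, io, ncr, network, simulate
from .errors import InputError

log = logging.getLogger("noduleseq")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))


@dataclass
class RunConfig:
    """Pipeline configuration. Thresholds default to the study's settings."""

    outdir: str = "results"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    de: bool = True
    ncr: bool = True
    dup_diverge: bool = True
    modules: bool = True
    # inputs (ignored for stages fed by a simulate stage)
    counts: str | None = None
    samples: str | None = None
    proteins: str | None = None
    dup_catalog: str | None = None
    dup_pairs: str | None = None
    annotation: str | None = None
    ct: str | None = None
    # parameters
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    low_count_mean: float = 2.0
    max_ncr_length: int = 150
    n_null_pairs: int = 10000
    null_level: float = 0.95
    beta: float = 6.0
    min_module_size: int = 20
    merge_cut_height: float = 0.45
    filter_min_samples: int = 3
    filter_threshold: float = 10.0
    enrichment_fdr: float = 0.05
    trait_p: float = 0.01
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, **info):
        report["stages"][stage] = info

    paths = {
        "counts": config.counts,
        "samples": config.samples,
        "proteins": config.proteins,
        "dup_catalog": config.dup_catalog,
        "dup_pairs": config.dup_pairs,
        "annotation": config.annotation,
        "ct": config.ct,
    }

    if config.simulate:
        gen_cfg = simulate.GeneratorConfig(**config.generator, seed=derive_seed(config.seed, "simulate"))
        bundle_dir = outdir / "bundle"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            simulate.generate_bundle(gen_cfg, bundle_dir)
        for key, fname in [
            ("counts", "counts.tsv"), ("samples", "samples.tsv"), ("proteins", "proteins.fasta"),
            ("dup_catalog", "dup_catalog.tsv"), ("dup_pairs", "dup_pairs.tsv"),
            ("annotation", "annotation.tsv"), ("ct", "ct.tsv"),
        ]:
            paths[key] = str(bundle_dir / fname)
        record(
            "simulate",
            params={**dataclasses.asdict(gen_cfg)},
            outputs={k: _hash_file(Path(v)) for k, v in paths.items() if v},
            warnings=[str(w.message) for w in wlist],
        )

    for key in ("counts", "samples"):
        if any([config.de, config.dup_diverge, config.modules]):
            if not paths[key]:
                raise InputError(f"{key}: no input configured")
            if not Path(paths[key]).exists():
                raise InputError(f"{key}: file not found: {paths[key]}")

    counts = samples = factors = de_results = None
    if config.de or config.dup_diverge or config.modules:
        counts = io.read_counts(paths["counts"])
        samples = io.read_samples(paths["samples"])
        factors = expression.compute_size_factors(counts)

    if config.de:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            de_results = expression.test_differential_expression(
                counts, factors, samples,
                lfc_threshold=config.lfc_threshold, alpha=config.alpha,
                low_count_mean=config.low_count_mean,
            )
            qc = expression.replicate_qc(counts, factors, samples)
        io.write_tsv(de_results, outdir / "de_results.tsv", index_label="gene_id")
        io.write_json(
            {
                "correlation": qc.correlation.round(6).to_dict(),
                "merges": qc.merges.tolist(),
                "sample_order": qc.sample_order,
                "pca": qc.pca.round(6).to_dict(),
                "explained_variance_ratio": list(qc.explained_variance_ratio),
            },
            outdir / "qc_report.json",
        )
        record(
            "de",
            inputs={k: _hash_file(Path(paths[k])) for k in ("counts", "samples")},
            params={"lfc_threshold": config.lfc_threshold, "alpha": config.alpha,
                    "low_count_mean": config.low_count_mean},
            n_genes=len(de_results),
            n_de=int(de_results["status"].isin(["de_up", "de_down"]).sum()),
            n_low_count=int((de_results["status"] == "low_count").sum()),
            warnings=[str(w.message) for w in wlist],
        )

    if config.ncr:
        if not paths["proteins"] or not Path(paths["proteins"]).exists():
            raise InputError(f"proteins: file not found: {paths['proteins']}")
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            records = io.read_fasta(paths["proteins"])
            cands = ncr.scan_ncr_candidates(records, max_length=config.max_ncr_length)
            table, summary = ncr.adjudicate_ncr(
                cands, de_results, lfc_threshold=config.lfc_threshold, alpha=config.alpha
            )
        io.write_tsv(table, outdir / "ncr_candidates.tsv")
        io.write_json(summary, outdir / "ncr_report.json")
        record(
            "ncr",
            inputs={"proteins": _hash_file(Path(paths["proteins"]))},
            params={"max_length": config.max_ncr_length},
            n_candidates=len(table),
            summary=summary,
            warnings=[str(w.message) for w in wlist],
        )

    if config.dup_diverge:
        for key in ("dup_catalog", "dup_pairs"):
            if not paths[key] or not Path(paths[key]).exists():
                raise InputError(f"{key}: file not found: {paths[key]}")
        catalog = io.read_duplication_catalog(paths["dup_catalog"])
        pairs = io.read_duplicate_pairs(paths["dup_pairs"])
        if de_results is None and config.de:
            de_results = io.read_tsv(outdir / "de_results.tsv", index_col="gene_id")
        deg = (
            list(de_results.index[de_results["status"].isin(["de_up", "de_down"])])
            if de_results is not None
            else []
        )
        expr_log = expression.log_normalized(counts, factors)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cut = duplication.null_correlation_cutoff(
                expr_log, n_pairs=config.n_null_pairs, level=config.null_level,
                seed=derive_seed(config.seed, "dup-null"),
            )
            pair_div, mode_frac = duplication.classify_pair_divergence(
                pairs, expr_log, cut, de_genes=deg if deg else None
            )
            if deg:
                mode_table, global_test = duplication.mode_enrichment_table(deg, catalog)
                io.write_tsv(mode_table, outdir / "mode_enrichment.tsv")
            else:
                global_test = None
        io.write_tsv(pair_div, outdir / "pair_divergence.tsv")
        io.write_tsv(mode_frac, outdir / "pair_divergence_by_mode.tsv")
        io.write_json(
            {
                "cutoff": cut.cutoff, "level": cut.level, "seed": cut.seed,
                "n_sampled": int(cut.samples.size), "exhaustive": cut.exhaustive,
                "n_constant_skipped": cut.n_constant_skipped,
                "r_summary": {
                    "mean": float(cut.samples.mean()),
                    "q05": float(pd.Series(cut.samples).quantile(0.05)),
                    "q95": float(pd.Series(cut.samples).quantile(0.95)),
                },
            },
            outdir / "null_cutoff.json",
        )
        record(
            "dup_diverge",
            inputs={k: _hash_file(Path(paths[k])) for k in ("dup_catalog", "dup_pairs")},
            params={"n_pairs": config.n_null_pairs, "level": config.null_level},
            cutoff=cut.cutoff,
            n_pairs_classified=len(pair_div),
            global_test=global_test,
            warnings=[str(w.message) for w in wlist],
        )

    if config.modules:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            expr = network.transform_and_filter(
                counts, factors,
                min_samples=config.filter_min_samples, threshold=config.filter_threshold,
            )
            adj = network.adjacency_signed_hybrid(expr, beta=config.beta)
            tom = network.topological_overlap(adj)
            assignment = network.detect_modules(
                tom, expr,
                min_module_size=config.min_module_size,
                merge_cut_height=config.merge_cut_height,
            )
            non_grey = sorted(set(assignment) - {"grey"})
            if non_grey:
                eig, varexp = network.module_eigengenes(expr, assignment)
                traits = network.encode_traits(samples.loc[expr.columns])
                mt = network.module_trait_correlation(eig, traits, p_threshold=config.trait_p)
                io.write_tsv(eig, outdir / "eigengenes.tsv", index_label="module")
                io.write_tsv(mt, outdir / "module_trait.tsv")
            enrich_frames = []
            if paths["annotation"] and Path(paths["annotation"]).exists():
                ann = io.read_annotation(paths["annotation"])
                universe = list(expr.index)
                for mod in non_grey:
                    genes = assignment.index[assignment == mod]
                    e = network.hypergeometric_enrichment(
                        genes, ann, universe, fdr_threshold=config.enrichment_fdr
                    )
                    e.insert(0, "module", mod)
                    enrich_frames.append(e)
            if enrich_frames:
                io.write_tsv(pd.concat(enrich_frames, ignore_index=True), outdir / "enrichment.tsv")
        io.write_tsv(assignment.to_frame(), outdir / "modules.tsv", index_label="gene_id")
        sizes = assignment.value_counts().to_dict()
        io.write_json(
            {"module_sizes": sizes, "n_modules": len(non_grey), "n_genes_filtered": len(assignment)},
            outdir / "module_summary.json",
        )
        record(
            "modules",
            inputs={"counts": _hash_file(Path(paths["counts"]))},
            params={"beta": config.beta, "min_module_size": config.min_module_size,
                    "merge_cut_height": config.merge_cut_height},
            n_genes_filtered=len(assignment),
            n_modules=len(non_grey),
            module_sizes=sizes,
            warnings=[str(w.message) for w in wlist],
        )

    io.write_json(report, outdir / "run_report.json")
    return report
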