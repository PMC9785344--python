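"""Gene-duplication mode enrichment and duplicate-pair expression divergence.

Genes are classified by duplication mode (whole-genome [WGD], tandem [TD],
proximal [PD], transposed [RD], dispersed [DSD], non-duplicated [ND]). The
mode distribution of differentially expressed genes is compared against the
expressed background with a chi-squared goodness-of-fit test plus per-mode
two-tailed Fisher exact tests. Duplicate pairs are called diverged in
expression when their profile correlation falls below a resampled null
cutoff: the empirical 95% quantile of Pearson r over randomly chosen gene
pairs (the cutoff is always recomputed from data, never hard-coded).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .simulate import DUPLICATION_MODES


def tabulate_mode_distribution(gene_set, catalog: pd.Series) -> dict:
    """Per-mode counts and proportions for a gene set against a mode catalog.

    Genes absent from the catalog are counted separately as unclassified and
    excluded from the proportions.
    """
    genes = list(gene_set)
    if not genes:
        raise InputError("gene set is empty")
    in_cat = [g for g in genes if g in catalog.index]
    if not in_cat:
        raise InputError("no gene in the set appears in the duplication catalog")
    modes = catalog.loc[in_cat]
    counts = {m: int((modes == m).sum()) for m in DUPLICATION_MODES}
    n = len(in_cat)
    return {
        "counts": counts,
        "proportions": {m: counts[m] / n for m in DUPLICATION_MODES},
        "n_classified": n,
        "n_unclassified": len(genes) - n,
    }


def test_global_distribution(deg_counts, background_proportions) -> dict:
    """Chi-squared goodness of fit of observed mode counts against background proportions."""
    obs = np.asarray(deg_counts, dtype=float)
    props = np.asarray(background_proportions, dtype=float)
    if obs.shape != props.shape:
        raise InputError("observed counts and background proportions must align")
    expected = obs.sum() * props / props.sum()
    if (expected <= 0).any():
        raise InputError("zero expected count in some category; pool categories before testing")
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = len(obs) - 1
    return {"statistic": stat, "df": dof, "p": float(stats.chi2.sf(stat, dof))}


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-tailed Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities no larger than the observed
    table's, with ties resolved by exact integer arithmetic (the per-table
    weights C(r1, k) * C(r2, c1 - k) share a common denominator, so integer
    comparison is exact). The odds ratio is ad/bc with a Haldane 0.5
    correction when any cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise InputError("table cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = sum(
        w for k in range(kmin, kmax + 1) if (w := math.comb(r1, k) * math.comb(r2, c1 - k)) <= w_obs
    )
    p = num / math.comb(n, c1) if n else 1.0
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(min(p, 1.0))


def test_mode_enrichment(
    mode: str,
    deg_counts: dict,
    background_counts: dict,
    exclude_degs_from_background: bool = False,
) -> dict:
    """Per-mode 2x2 Fisher test: mode membership vs DEG membership.

    By default the background includes the DEGs (DEGs are themselves
    expressed genes); set ``exclude_degs_from_background`` to test against
    the complement instead.
    """
    a = int(deg_counts[mode])
    b = int(sum(deg_counts.values()) - a)
    bg_mode = int(background_counts[mode])
    bg_rest = int(sum(background_counts.values()) - bg_mode)
    if exclude_degs_from_background:
        bg_mode -= a
        bg_rest -= b
        if bg_mode < 0 or bg_rest < 0:
            raise InputError("background must contain the DEG set when excluding it")
    odds, p = fisher_exact_two_tailed(a, b, bg_mode, bg_rest)
    return {"mode": mode, "table": [[a, b], [bg_mode, bg_rest]], "odds_ratio": odds, "p": p}


def mode_enrichment_table(
    deg_genes,
    catalog: pd.Series,
    background_genes=None,
    exclude_degs_from_background: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full mode-distribution comparison: per-mode Fisher tests + global chi-squared.

    ``background_genes`` defaults to every gene in the catalog.
    """
    deg_tab = tabulate_mode_distribution(deg_genes, catalog)
    bg_genes = list(background_genes) if background_genes is not None else list(catalog.index)
    bg_tab = tabulate_mode_distribution(bg_genes, catalog)

    rows = []
    for m in DUPLICATION_MODES:
        res = test_mode_enrichment(
            m, deg_tab["counts"], bg_tab["counts"], exclude_degs_from_background
        )
        rows.append(
            {
                "mode": m,
                "deg_count": deg_tab["counts"][m],
                "deg_pct": 100.0 * deg_tab["proportions"][m],
                "background_pct": 100.0 * bg_tab["proportions"][m],
                "odds_ratio": res["odds_ratio"],
                "fisher_p": res["p"],
            }
        )
    table = pd.DataFrame(rows)
    global_test = test_global_distribution(
        [deg_tab["counts"][m] for m in DUPLICATION_MODES],
        [bg_tab["proportions"][m] for m in DUPLICATION_MODES],
    )
    global_test["n_deg_classified"] = deg_tab["n_classified"]
    global_test["n_deg_unclassified"] = deg_tab["n_unclassified"]
    global_test["n_background_classified"] = bg_tab["n_classified"]
    return table, global_test


# ---------------------------------------------------------------------------
# Expression-divergence null and pair classification


@dataclass
class NullCutoff:
    """Resampled null distribution of pair correlations and its upper quantile."""

    samples: np.ndarray
    level: float
    cutoff: float
    seed: int
    n_constant_skipped: int
    exhaustive: bool = False


def null_correlation_cutoff(
    expression: pd.DataFrame,
    n_pairs: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> NullCutoff:
    """Empirical null for pair correlations from randomly chosen gene pairs.

    Pairs are drawn uniformly without replacement among unordered distinct
    pairs of non-constant genes; the cutoff is the inclusive (type-7)
    ``level`` quantile of the sampled Pearson r values. If fewer than
    ``n_pairs`` distinct pairs exist, all pairs are used (with a warning).
    """
    x = expression.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise InputError("need at least 2 samples to correlate profiles")
    sd = x.std(axis=1)
    keep = sd > 0
    n_skipped = int((~keep).sum())
    x = x[keep]
    g = x.shape[0]
    if g < 2:
        raise InputError("need at least 2 non-constant gene profiles")

    total = g * (g - 1) // 2
    rng = np.random.default_rng(seed)
    if total <= n_pairs:
        warnings.warn(f"only {total} distinct pairs available; sampling exhaustively")
        ii, jj = np.triu_indices(g, k=1)
        exhaustive = True
    else:
        codes: set[int] = set()
        while len(codes) < n_pairs:
            need = n_pairs - len(codes)
            i = rng.integers(0, g, size=2 * need + 8)
            j = rng.integers(0, g, size=2 * need + 8)
            for a, b in zip(i, j):
                if a == b:
                    continue
                lo, hi = (a, b) if a < b else (b, a)
                codes.add(int(lo) * g + int(hi))
                if len(codes) >= n_pairs:
                    break
        arr = np.fromiter(sorted(codes), dtype=np.int64)
        ii, jj = arr // g, arr % g
        exhaustive = False

    z = x - x.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    r = np.einsum("ij,ij->i", z[ii], z[jj])
    r = np.clip(r, -1.0, 1.0)
    cutoff = float(np.quantile(r, level, method="linear"))
    return NullCutoff(r, level, cutoff, seed, n_skipped, exhaustive)


def classify_pair_divergence(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    cutoff: NullCutoff | float,
    de_genes=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label duplicate pairs conserved/diverged by profile correlation.

    A pair is diverged iff r < cutoff, undefined when either profile is
    constant; pairs with members missing from the matrix are skipped with a
    warning. When ``de_genes`` is given, only pairs with at least one
    differentially expressed member are classified. Returns the labeled pair
    table and per-mode diverged fractions over defined pairs.
    """
    cut = cutoff.cutoff if isinstance(cutoff, NullCutoff) else float(cutoff)
    de_set = set(de_genes) if de_genes is not None else None
    x = expression
    rows = []
    n_skipped = 0
    for rec in pairs.itertuples(index=False):
        g1, g2, mode = rec.gene1, rec.gene2, getattr(rec, "mode", "NA")
        if g1 not in x.index or g2 not in x.index:
            n_skipped += 1
            continue
        if de_set is not None and g1 not in de_set and g2 not in de_set:
            continue
        a = x.loc[g1].to_numpy(dtype=float)
        b = x.loc[g2].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            rows.append((g1, g2, mode, np.nan, "undefined"))
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append((g1, g2, mode, r, "diverged" if r < cut else "conserved"))
    if n_skipped:
        warnings.warn(f"{n_skipped} pairs skipped: member missing from the expression matrix")
    out = pd.DataFrame(rows, columns=["gene1", "gene2", "mode", "r", "divergence"])
    defined = out[out["divergence"] != "undefined"]
    if len(defined):
        frac = (
            defined.assign(div=defined["divergence"] == "diverged")
            .groupby("mode")["div"]
            .agg(n_pairs="size", diverged_fraction="mean")
            .reset_index()
        )
    else:
        frac = pd.DataFrame(columns=["mode", "n_pairs", "diverged_fraction"])
    return out, frac
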