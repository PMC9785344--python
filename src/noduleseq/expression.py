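"""Count normalization, replicate QC, and differential expression.

The differential-expression test is a deliberately simple negative-binomial
Wald test: per-gene method-of-moments dispersion shrunk halfway toward a
parametric mean-dispersion trend alpha(mu) = a0 + a1/mu, group means on
median-of-ratios normalized counts, and a t reference distribution with
n1 + n2 - 2 degrees of freedom as a small-sample correction. Genes are called
differentially expressed when |log2FC| > 1 and the Benjamini-Hochberg
adjusted p-value is below 0.05 (the low-BNF group is the reference, so a
positive log2FC means higher expression in high-fixation genotypes). Genes
whose raw mean count across samples is below 2 are excluded as low counts
before testing and before the BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, DesignError, InputError

LFC_THRESHOLD = 1.0
ALPHA = 0.05
LOW_COUNT_MEAN = 2.0


# ---------------------------------------------------------------------------
# Normalization


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to unit geometric mean.

    For each sample j, s_j is the median over genes (restricted to genes with
    all-positive counts) of count_ij / geometric-mean_i.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise DegenerateInputError(
            "no gene has positive counts in every sample; median-of-ratios is undefined "
            "(consider a pseudo-reference on nonzero genes)"
        )
    logm = np.log(mat[positive])
    log_geomean = logm.mean(axis=1)
    ratios = np.exp(logm - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    s = s / np.exp(np.mean(np.log(s)))  # unit geometric mean
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return counts.div(factors.reindex(counts.columns), axis=1)


def log_normalized(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(normalized + 1), the working transform for QC and correlation."""
    return np.log2(normalize_counts(counts, factors) + 1.0)


# ---------------------------------------------------------------------------
# Replicate QC


@dataclass
class QCReport:
    """Pairwise correlation, d = 1 - r complete-linkage dendrogram, and PCA."""

    correlation: pd.DataFrame  # sample x sample Pearson r (NaN where undefined)
    merges: np.ndarray  # scipy linkage matrix on d = 1 - r, complete linkage
    sample_order: list[str]
    pca: pd.DataFrame  # samples x (PC1, PC2)
    explained_variance_ratio: tuple[float, float]


def replicate_qc(counts: pd.DataFrame, factors: pd.Series, meta: pd.DataFrame | None = None) -> QCReport:
    """Pearson-correlation QC on log2(normalized + 1) profiles.

    Constant sample columns yield undefined (NaN) correlations, reported as
    missing; for clustering those distances fall back to the maximum (1).
    """
    if counts.shape[1] < 3:
        raise InputError("replicate QC needs at least 3 samples")
    ln = log_normalized(counts, factors)
    x = ln.to_numpy()
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[np.ix_(sd == 0, np.arange(len(sd)))] = np.nan
    r[np.ix_(np.arange(len(sd)), sd == 0)] = np.nan
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=counts.columns, columns=counts.columns)

    d = 1.0 - np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    merges = linkage(squareform(d, checks=False), method="complete")

    # PCA on the centered, gene-standardized matrix (constant genes dropped)
    g_sd = x.std(axis=1)
    keep = g_sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / g_sd[keep][:, None]
    zc = z - z.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    coords = (vt[:2].T * s[:2]) if s.size >= 2 else np.zeros((x.shape[1], 2))
    evr = tuple((s[:2] ** 2 / (s**2).sum()).tolist()) if s.size >= 2 else (0.0, 0.0)
    pca = pd.DataFrame(coords, index=counts.columns, columns=["PC1", "PC2"])
    return QCReport(corr, merges, list(counts.columns), pca, evr)


# ---------------------------------------------------------------------------
# Differential expression


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha(mu) = a0 + a1/mu over genes, clipped to >= 0."""
    x = np.column_stack([np.ones_like(mu), 1.0 / np.maximum(mu, 1e-8)])
    coef, *_ = np.linalg.lstsq(x, alpha, rcond=None)
    return float(max(coef[0], 1e-8)), float(max(coef[1], 0.0))


def test_differential_expression(
    counts: pd.DataFrame,
    factors: pd.Series,
    meta: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    low_count_mean: float = LOW_COUNT_MEAN,
) -> pd.DataFrame:
    """Negative-binomial Wald test of high vs low BNF class, per gene.

    Returns a frame indexed by gene with base_mean, log2fc, se, p, padj and
    status in {de_up, de_down, not_de, low_count}. Low-count genes (raw mean
    < ``low_count_mean``) carry no p-value and are excluded from the BH
    family.
    """
    levels = meta.loc[counts.columns, "bnf_class"]
    high = counts.columns[(levels == "high").to_numpy()]
    low = counts.columns[(levels == "low").to_numpy()]
    if len(high) < 2 or len(low) < 2:
        raise DesignError("both bnf_class levels must be present with >= 2 samples each")

    raw_mean = counts.mean(axis=1).to_numpy()
    q = normalize_counts(counts, factors)
    qh, ql = q[high].to_numpy(), q[low].to_numpy()
    nh, nl = qh.shape[1], ql.shape[1]

    mu_h = qh.mean(axis=1)
    mu_l = ql.mean(axis=1)
    base_mean = q.mean(axis=1).to_numpy()

    tested = raw_mean >= low_count_mean

    # method-of-moments dispersion, pooled within groups, shot noise removed
    inv_s = (1.0 / factors.reindex(counts.columns)).to_numpy()
    inv_s_h = inv_s[(levels == "high").to_numpy()].mean()
    inv_s_l = inv_s[(levels == "low").to_numpy()].mean()
    var_pool = (qh.var(axis=1, ddof=1) * (nh - 1) + ql.var(axis=1, ddof=1) * (nl - 1)) / (nh + nl - 2)
    mu_pool = (mu_h * nh + mu_l * nl) / (nh + nl)
    shot = mu_pool * (inv_s_h * nh + inv_s_l * nl) / (nh + nl)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_mom = (var_pool - shot) / np.maximum(mu_pool, 1e-12) ** 2
    disp_mom = np.clip(disp_mom, 1e-8, 10.0)

    fit_mask = tested & (mu_pool > 0)
    if fit_mask.sum() >= 10:
        a0, a1 = _fit_dispersion_trend(mu_pool[fit_mask], disp_mom[fit_mask])
    else:
        a0, a1 = float(np.median(disp_mom[fit_mask])) if fit_mask.any() else 0.1, 0.0
    disp_trend = np.clip(a0 + a1 / np.maximum(mu_pool, 1e-8), 1e-8, 10.0)
    disp = 0.5 * disp_mom + 0.5 * disp_trend  # 50% shrinkage toward the trend

    pc = 0.5  # pseudocount stabilizing the fold change at low means
    log2fc = np.log2((mu_h + pc) / (mu_l + pc))
    var_h = (mu_h * inv_s_h + disp * mu_h**2) / nh
    var_l = (mu_l * inv_s_l + disp * mu_l**2) / nl
    ln2 = np.log(2.0)
    se = np.sqrt(var_h / np.maximum(mu_h + pc, 1e-12) ** 2 + var_l / np.maximum(mu_l + pc, 1e-12) ** 2) / ln2
    se = np.maximum(se, 1e-12)

    # t reference with n1 + n2 - 2 df: small-sample correction for the Wald statistic
    dof = nh + nl - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(wald), df=dof)
    p = np.where(tested, p, np.nan)

    padj = np.full_like(p, np.nan)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    status = np.where(tested, "not_de", "low_count")
    sig = tested & (np.abs(log2fc) > lfc_threshold) & (padj < alpha)
    status = np.where(sig & (log2fc > 0), "de_up", status)
    status = np.where(sig & (log2fc < 0), "de_down", status)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(tested, log2fc, np.nan),
            "se": np.where(tested, se, np.nan),
            "p": p,
            "padj": padj,
            "status": status,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# Report operations


def rank_by_length_normalized_expression(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Mean reads across samples divided by sequence length, descending.

    Ties are broken by gene id. Missing lengths for expressed genes raise.
    """
    lengths = lengths.reindex(counts.index)
    missing = lengths.index[lengths.isna()]
    if len(missing):
        raise InputError(f"missing lengths for genes: {list(missing[:10])}")
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    score = counts.mean(axis=1) / lengths
    out = pd.DataFrame({"mean_reads": counts.mean(axis=1), "length": lengths, "score": score})
    # ascending id first, then a stable descending sort on score -> ties break by gene id
    return out.sort_index(kind="mergesort").sort_values("score", ascending=False, kind="mergesort")


def flag_unconfirmed_genes(reference_ids, evidence_ids) -> list[str]:
    """Genes present in the reference annotation but absent from the evidence set."""
    return sorted(set(reference_ids) - set(evidence_ids))


def relative_expression_ddct(
    ct: pd.DataFrame, reference_gene: str, calibrator_sample: str
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Technical replicates are averaged per (sample, gene) before dCt =
    Ct_target - Ct_reference; ddCt is taken against the calibrator sample and
    fold = 2^-ddCt (so the calibrator's fold is exactly 1).
    """
    mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    if reference_gene not in mean_ct.columns or mean_ct[reference_gene].isna().any():
        raise InputError(f"reference gene {reference_gene!r} must be measured in every sample")
    if calibrator_sample not in mean_ct.index:
        raise InputError(f"calibrator sample {calibrator_sample!r} absent from the Ct table")
    dct = mean_ct.drop(columns=[reference_gene]).sub(mean_ct[reference_gene], axis=0)
    ddct = dct.sub(dct.loc[calibrator_sample], axis=1)
    fold = np.exp2(-ddct)
    out = pd.concat(
        {"dct": dct.stack(), "ddct": ddct.stack(), "fold": fold.stack()}, axis=1
    ).reset_index()
    return out.rename(columns={"level_0": "sample", "level_1": "gene"})


def compare_phenotype_groups(
    meta: pd.DataFrame,
    value_col: str = "ethylene",
    group_col: str = "bnf_class",
    greater: str = "high",
    mass_col: str = "fresh_mass",
    ploidy_col: str = "ploidy",
) -> dict:
    """Phenotype-level group comparison.

    One-tailed Mann-Whitney U test that the ``greater`` group's trait exceeds
    the other group's (exact enumeration when both groups are small and
    tie-free, midrank normal approximation otherwise), per-ploidy OLS of fresh
    mass on the trait, and violin-style summary statistics per group.
    """
    levels = meta[group_col].unique()
    if len(levels) != 2:
        raise InputError("exactly two groups required")
    other = [lv for lv in levels if lv != greater][0]
    a = meta.loc[meta[group_col] == greater, value_col].to_numpy(dtype=float)
    b = meta.loc[meta[group_col] == other, value_col].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 observations")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 12 and not has_ties) else "asymptotic"
    u = stats.mannwhitneyu(a, b, alternative="greater", method=method)

    regressions = {}
    if mass_col in meta.columns and ploidy_col in meta.columns:
        for ploidy, sub in meta.groupby(ploidy_col):
            if len(sub) >= 3 and sub[value_col].nunique() > 1:
                fit = stats.linregress(sub[value_col], sub[mass_col])
                regressions[str(ploidy)] = {
                    "slope": float(fit.slope),
                    "intercept": float(fit.intercept),
                    "r_squared": float(fit.rvalue**2),
                    "p": float(fit.pvalue),
                }

    def _summary(v: np.ndarray) -> dict:
        return {
            "n": int(len(v)),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "min": float(v.min()),
            "max": float(v.max()),
        }

    return {
        "u_statistic": float(u.statistic),
        "p_one_tailed": float(u.pvalue),
        "method": method,
        "alternative": f"{greater} > {other}",
        "group_summaries": {greater: _summary(a), str(other): _summary(b)},
        "mass_regressions_by_ploidy": regressions,
    }
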