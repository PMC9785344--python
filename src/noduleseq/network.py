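"""Signed-hybrid co-expression modules, eigengenes, traits, and enrichment.

The workflow mirrors weighted co-expression network analysis in simplified
form: genes are filtered on a log-based transform of normalized counts,
pairwise Pearson correlations are soft-thresholded into a signed-hybrid
adjacency (negative correlations zeroed, positives raised to power beta),
converted to a topological overlap matrix (TOM), and clustered by average
linkage on 1 - TOM. Initial clusters come from a static tree cut at a high
quantile of the merge heights; clusters below the minimum size fall into the
unassigned "grey" pool and modules with similar eigengenes are merged. Module
eigengenes (first principal component of the standardized module submatrix)
are correlated with sample traits, and per-module annotation-term enrichment
uses the upper-tail hypergeometric test with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .expression import normalize_counts

#: Module label sequence, largest module first ("grey" is reserved for unassigned).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
)

DEFAULT_BETA = 6.0
DEFAULT_MIN_MODULE_SIZE = 20
DEFAULT_MERGE_CUT_HEIGHT = 0.45
DEFAULT_FILTER_MIN_SAMPLES = 3
DEFAULT_FILTER_THRESHOLD = 10.0
DEFAULT_CUT_HEIGHT = 0.99


def transform_and_filter(
    counts: pd.DataFrame,
    factors: pd.Series,
    min_samples: int = DEFAULT_FILTER_MIN_SAMPLES,
    threshold: float = DEFAULT_FILTER_THRESHOLD,
) -> pd.DataFrame:
    """log2(normalized + 1) transform, then the occurrence filter.

    A gene is kept iff its transformed value is >= ``threshold`` in at least
    ``min_samples`` samples (the boundary count is inclusive). The log
    transform is a documented stand-in for a variance-stabilizing transform;
    it shares its scale (log2 of normalized counts) so the same threshold
    semantics apply.
    """
    t = np.log2(normalize_counts(counts, factors) + 1.0)
    keep = (t >= threshold).sum(axis=1) >= min_samples
    if not keep.any():
        raise InputError("no gene passes the expression filter")
    return t.loc[keep]


def adjacency_signed_hybrid(expression: pd.DataFrame, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Signed-hybrid adjacency: a_ij = cor(i,j)^beta for positive cor, else 0."""
    if expression.shape[1] < 3:
        raise InputError("need at least 3 samples")
    x = expression.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant gene profiles; their adjacency is zeroed")
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.where(cor > 0, cor, 0.0) ** beta
    np.fill_diagonal(adj, 1.0)
    adj[sd == 0, :] = 0.0
    adj[:, sd == 0] = 0.0
    np.fill_diagonal(adj, 1.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with k_i the off-diagonal row sum; the diagonal is 1.
    """
    a = adjacency.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _standardize_genes(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.zeros_like(x)
    ok = sd[:, 0] > 0
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    return z


def _eigengene(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector of the gene-standardized submatrix.

    Unit norm over samples, sign oriented to correlate positively with the
    module's mean expression profile; returns (eigengene, variance explained).
    """
    z = _standardize_genes(x)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    varexp = float(s[0] ** 2 / (s**2).sum()) if (s**2).sum() > 0 else 0.0
    mean_profile = x.mean(axis=0)
    mc = mean_profile - mean_profile.mean()
    if float(e @ mc) < 0:
        e = -e
    return e, varexp


def module_eigengenes(
    expression: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-module eigengenes (modules x samples) and variance-explained fractions."""
    eigs, varexps = {}, {}
    for mod in sorted(set(assignment) - {"grey"}):
        genes = assignment.index[assignment == mod]
        sub = expression.loc[genes].to_numpy(dtype=float)
        if (sub.std(axis=1) == 0).all():
            raise InputError(f"module {mod!r} consists only of constant genes")
        e, v = _eigengene(sub)
        eigs[mod], varexps[mod] = e, v
    eig_df = pd.DataFrame(eigs, index=expression.columns).T
    return eig_df, pd.Series(varexps, name="variance_explained")


def detect_modules(
    tom: np.ndarray,
    expression: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    merge_cut_height: float = DEFAULT_MERGE_CUT_HEIGHT,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> pd.Series:
    """Assign genes to modules from a TOM.

    Average-linkage clustering on 1 - TOM; initial clusters from a static cut
    of the dendrogram at absolute height ``cut_height`` (TOM dissimilarities
    lie in [0, 1], and unrelated genes merge very close to 1, so a cut just
    below 1 isolates coherent branches); clusters smaller than
    ``min_module_size`` go to "grey"; modules whose eigengene dissimilarity
    (1 - cor) is below ``merge_cut_height`` are merged iteratively (a height
    of 0 disables merging). Final labels are color names ordered by module
    size, largest first.
    """
    genes = expression.index
    n = len(genes)
    if tom.shape != (n, n):
        raise InputError("TOM shape does not match the expression matrix")
    if n < min_module_size:
        return pd.Series(["grey"] * n, index=genes, name="module")
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    if np.allclose(heights, heights[0]):
        warnings.warn("degenerate TOM: all merge heights equal; single module")
        labels = np.ones(n, dtype=int)
    else:
        labels = fcluster(z, t=cut_height, criterion="distance")

    assignment = pd.Series(labels.astype(object), index=genes, name="module")
    sizes = assignment.value_counts()
    small = sizes.index[sizes < min_module_size]
    assignment[assignment.isin(small)] = "grey"

    if merge_cut_height > 0:
        while True:
            mods = sorted(set(assignment) - {"grey"})
            if len(mods) < 2:
                break
            eig_df, _ = module_eigengenes(expression, assignment)
            cor = np.corrcoef(eig_df.loc[mods].to_numpy())
            np.fill_diagonal(cor, -np.inf)
            i, j = np.unravel_index(np.argmax(cor), cor.shape)
            if 1.0 - cor[i, j] >= merge_cut_height:
                break
            keep, drop = (mods[i], mods[j]) if (assignment == mods[i]).sum() >= (
                assignment == mods[j]
            ).sum() else (mods[j], mods[i])
            assignment[assignment == drop] = keep

    # rename by size, largest first
    final = sorted(set(assignment) - {"grey"})
    order = sorted(final, key=lambda m: (-(assignment == m).sum(), str(m)))
    rename = {
        m: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, m in enumerate(order)
    }
    return assignment.map(lambda m: rename.get(m, "grey")).rename("module")


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, p_threshold: float = 0.01
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each numeric trait.

    Binary traits should be coded 0/1 beforehand (see ``encode_traits``).
    Constant traits yield missing correlations.
    """
    if eigengenes.shape[1] < 3:
        raise InputError("need at least 3 samples")
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        for trait in traits.columns:
            t = traits[trait].reindex(eigengenes.columns).to_numpy(dtype=float)
            if np.isnan(t).any() or np.std(t) == 0:
                rows.append((mod, trait, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(e, t)
            rows.append((mod, trait, float(r), float(p), bool(p < p_threshold)))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p", "significant"])


def encode_traits(meta: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait matrix from sample metadata.

    bnf_class high = 1 / low = 0, ploidy 4n = 1 / 2n = 0, genotypes as
    one-hot indicators, numeric columns passed through.
    """
    out = pd.DataFrame(index=meta.index)
    if "bnf_class" in meta.columns:
        out["fixation"] = (meta["bnf_class"] == "high").astype(float)
    if "ploidy" in meta.columns:
        out["ploidy"] = (meta["ploidy"] == "4n").astype(float)
    for col in ("fresh_mass", "ethylene"):
        if col in meta.columns:
            out[col] = meta[col].astype(float)
    if "genotype" in meta.columns:
        for geno in sorted(meta["genotype"].unique()):
            out[f"genotype_{geno}"] = (meta["genotype"] == geno).astype(float)
    return out


def hypergeometric_enrichment(
    module_genes,
    annotation: pd.DataFrame,
    universe,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment for one module.

    For a term with K genes in the universe (N genes) and k of the module's
    n genes, p = P[X >= k] under the hypergeometric distribution; BH FDR is
    applied across terms. Terms with no universe genes are skipped with a
    warning.
    """
    universe = set(universe)
    module = set(module_genes) & universe
    if set(module_genes) - universe:
        raise InputError("module genes must be a subset of the universe")
    n, n_universe = len(module), len(universe)
    ann = annotation[annotation["gene_id"].isin(universe)]
    term_genes = ann.groupby("term_id")["gene_id"].agg(set)
    skipped = set(annotation["term_id"].unique()) - set(term_genes.index)
    if skipped:
        warnings.warn(f"{len(skipped)} terms have no genes in the universe; skipped")
    rows = []
    for term, genes in term_genes.items():
        big_k = len(genes)
        k = len(genes & module)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n)) if k > 0 else 1.0
        rows.append((term, k, big_k, n, n_universe, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["enriched"] = out["fdr"] < fdr_threshold
        out = out.sort_values(["p", "term_id"]).reset_index(drop=True)
    return out


def export_edge_list(
    adjacency: np.ndarray, gene_ids, threshold: float
) -> pd.DataFrame:
    """Edge list (gene1, gene2, adjacency) for edges with adjacency >= threshold.

    The threshold is a free parameter of the export; adjacency values lie in
    [0, 1].
    """
    ii, jj = np.triu_indices(len(gene_ids), k=1)
    w = adjacency[ii, jj]
    keep = w >= threshold
    ids = np.asarray(list(gene_ids))
    return pd.DataFrame({"gene1": ids[ii[keep]], "gene2": ids[jj[keep]], "adjacency": w[keep]})
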