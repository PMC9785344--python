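"""Normalization, QC, differential expression, and the small report operations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from noduleseq import expression as xp
from noduleseq.errors import DegenerateInputError, DesignError, InputError


def _counts(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=samples)


def _meta(classes, samples=None):
    samples = samples or [f"s{j}" for j in range(len(classes))]
    return pd.DataFrame({"bnf_class": classes}, index=pd.Index(samples, name="sample_id"))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = _counts([[10, 10], [5, 5], [100, 100]])
        assert np.allclose(xp.compute_size_factors(c), 1.0)

    def test_doubled_column_gives_factor_ratio_two(self):
        a = np.array([13, 7, 250, 31])
        c = _counts(np.column_stack([a, 2 * a]))
        s = xp.compute_size_factors(c)
        assert s["s1"] / s["s0"] == pytest.approx(2.0, rel=1e-9)

    def test_recovers_planted_library_size_ratios(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(3, 1, size=2000)
        libs = np.array([0.5, 1.0, 2.0, 1.0])
        counts = _counts(rng.poisson(mu[:, None] * libs[None, :]))
        s = xp.compute_size_factors(counts).to_numpy()
        ratio = s / s[1]
        assert np.allclose(ratio, libs / libs[1], rtol=0.05)

    def test_all_zero_rows_raise_degenerate_error(self):
        c = _counts([[0, 5], [3, 0]])
        with pytest.raises(DegenerateInputError, match="pseudo-reference"):
            xp.compute_size_factors(c)

    def test_idempotence_on_normalized_matrix(self):
        rng = np.random.default_rng(1)
        c = _counts(rng.poisson(50, size=(500, 6)) + 1)
        s = xp.compute_size_factors(c)
        renorm = xp.compute_size_factors(xp.normalize_counts(c, s))
        assert np.allclose(renorm, 1.0, atol=1e-6)


def _brute_force_complete_linkage(d):
    """Quadratic reference: repeatedly merge the closest clusters, distance = max pairwise."""
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if dist < best[0]:
                    best = (dist, (i, j))
        (i, j) = best[1]
        heights.append(best[0])
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestReplicateQC:
    def test_duplicated_samples_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(40, size=200)
        b = rng.poisson(40, size=200)
        c = _counts(np.column_stack([a, a, b]))
        qc = xp.replicate_qc(c, pd.Series(1.0, index=c.columns))
        assert qc.correlation.iloc[0, 1] == pytest.approx(1.0)
        assert qc.merges[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(qc.merges[0, 0]), int(qc.merges[0, 1])} == {0, 1}

    def test_complete_linkage_matches_brute_force(self):
        rng = np.random.default_rng(3)
        c = _counts(rng.poisson(30, size=(300, 8)) + 1)
        s = xp.compute_size_factors(c)
        qc = xp.replicate_qc(c, s)
        d = 1.0 - qc.correlation.to_numpy()
        np.fill_diagonal(d, 0.0)
        assert np.allclose(sorted(qc.merges[:, 2]), _brute_force_complete_linkage(d), atol=1e-10)

    def test_pca_separates_planted_groups(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(3, 1, 400)
        shift = np.exp2(rng.normal(0, 1.5, 400))
        cols = [rng.poisson(base) for _ in range(3)] + [rng.poisson(base * shift) for _ in range(3)]
        c = _counts(np.column_stack(cols))
        qc = xp.replicate_qc(c, xp.compute_size_factors(c))
        pc1 = qc.pca["PC1"].to_numpy()
        assert (pc1[:3] < 0).all() != (pc1[3:] < 0).all()  # groups on opposite sides

    def test_constant_sample_reported_missing_not_zero(self):
        c = _counts([[5, 5, 1], [5, 9, 1], [5, 2, 1]])
        qc = xp.replicate_qc(c, pd.Series(1.0, index=c.columns))
        assert np.isnan(qc.correlation.iloc[0, 1])
        assert qc.correlation.iloc[0, 0] == 1.0


class TestDifferentialExpression:
    def test_identical_groups_give_zero_lfc_not_de(self):
        block = np.tile([[20], [50], [400], [7]], (1, 6))
        c = _counts(block + np.tile([0, 1, 2], 2))  # jitter identical across the two groups
        meta = _meta(["high"] * 3 + ["low"] * 3)
        de = xp.test_differential_expression(c, pd.Series(1.0, index=c.columns), meta)
        assert np.allclose(de["log2fc"].abs(), 0.0, atol=1e-9)
        assert (de["status"] == "not_de").all()

    def test_low_count_gene_gets_no_pvalue(self):
        rng = np.random.default_rng(5)
        arr = rng.poisson(30, size=(50, 6))
        arr[0] = [1, 2, 1, 2, 1, 2]  # raw mean 1.5 < 2
        c = _counts(arr)
        meta = _meta(["high"] * 3 + ["low"] * 3)
        de = xp.test_differential_expression(c, xp.compute_size_factors(c), meta)
        assert de.iloc[0]["status"] == "low_count"
        assert np.isnan(de.iloc[0]["p"])

    def test_single_level_design_raises(self):
        c = _counts(np.ones((10, 4), dtype=int) * 5)
        with pytest.raises(DesignError):
            xp.test_differential_expression(c, pd.Series(1.0, index=c.columns), _meta(["high"] * 4))

    def test_null_type_one_error_rate_calibrated(self):
        """5,000-gene null bundles: fraction of p < 0.05 stays near nominal."""
        from noduleseq.simulate import GeneratorConfig, generate_counts

        fracs = []
        for seed in range(3):
            cfg = GeneratorConfig(
                n_genes=5000, n_genotypes_per_group=2, n_replicates=3,
                de_fraction=0.0, n_modules=0, seed=seed,
            )
            counts, samples, _ = generate_counts(cfg)
            de = xp.test_differential_expression(counts, xp.compute_size_factors(counts), samples)
            p = de["p"].dropna()
            fracs.append((p < 0.05).mean())
        assert all(0.035 <= f <= 0.065 for f in fracs)

    def test_bh_adjustment_invariants(self):
        rng = np.random.default_rng(6)
        c = _counts(rng.poisson(40, size=(300, 8)))
        meta = _meta(["high"] * 4 + ["low"] * 4)
        de = xp.test_differential_expression(c, xp.compute_size_factors(c), meta)
        tested = de["p"].notna()
        assert (de.loc[tested, "padj"] >= de.loc[tested, "p"] - 1e-15).all()
        assert (de.loc[tested, "padj"] <= 1.0).all()
        by_p = de.loc[tested].sort_values("p")
        assert (np.diff(by_p["padj"]) >= -1e-12).all()


class TestReportOps:
    def test_length_normalization_and_tie_breaking(self):
        c = _counts([[10, 10], [10, 10], [0, 0]], genes=["b_long", "a_short", "z_zero"])
        ranked = xp.rank_by_length_normalized_expression(
            c, pd.Series({"b_long": 200, "a_short": 100, "z_zero": 50})
        )
        assert list(ranked.index) == ["a_short", "b_long", "z_zero"]
        assert ranked.loc["a_short", "score"] == 2 * ranked.loc["b_long", "score"]
        assert ranked.loc["z_zero", "score"] == 0.0

    def test_rank_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(7)
        c = _counts(rng.poisson(20, size=(10, 4)))
        lengths = pd.Series(rng.integers(100, 2000, 10), index=c.index)
        ranked = xp.rank_by_length_normalized_expression(c, lengths)
        oracle = sorted(c.index, key=lambda g: (-(c.loc[g].mean() / lengths[g]), g))
        assert list(ranked.index) == oracle

    def test_missing_length_raises_listing_offenders(self):
        c = _counts([[1, 1], [2, 2]], genes=["a", "b"])
        with pytest.raises(InputError, match="b"):
            xp.rank_by_length_normalized_expression(c, pd.Series({"a": 100}))

    def test_unconfirmed_gene_set_difference(self):
        assert xp.flag_unconfirmed_genes({"a", "b", "c"}, {"b"}) == ["a", "c"]
        assert xp.flag_unconfirmed_genes({"a"}, {"a"}) == []
        rng = np.random.default_rng(8)
        ref = set(map(str, rng.integers(0, 2000, 1000)))
        ev = set(map(str, rng.integers(0, 2000, 1000)))
        assert xp.flag_unconfirmed_genes(ref, ev) == sorted(ref - ev)


class TestDeltaDeltaCt:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])

    def test_uniform_ddct_gives_unit_folds(self):
        rows = [(s, g, 1, ct) for s in ("s1", "s2") for g, ct in [("ref", 15.0), ("t", 20.0)]]
        rel = xp.relative_expression_ddct(self._table(rows), "ref", "s1")
        assert np.allclose(rel["fold"], 1.0)

    def test_hand_computed_fourfold(self):
        rows = [
            ("cal", "ref", 1, 15.0), ("cal", "t", 1, 22.0),
            ("s", "ref", 1, 15.0), ("s", "t", 1, 20.0),
        ]
        rel = xp.relative_expression_ddct(self._table(rows), "ref", "cal").set_index("sample")
        assert rel.loc["s", "fold"] == pytest.approx(4.0)  # ddCt = -2
        assert rel.loc["cal", "fold"] == pytest.approx(1.0)

    def test_replicates_averaged_before_dct(self):
        rows = [
            ("cal", "ref", r, 15.0) for r in (1, 2, 3)
        ] + [("cal", "t", r, ct) for r, ct in [(1, 21.0), (2, 22.0), (3, 23.0)]] + [
            ("s", "ref", r, 15.0) for r in (1, 2, 3)
        ] + [("s", "t", r, 20.0) for r in (1, 2, 3)]
        rel = xp.relative_expression_ddct(self._table(rows), "ref", "cal").set_index("sample")
        assert rel.loc["s", "fold"] == pytest.approx(2.0 ** (22.0 - 20.0))

    def test_missing_reference_measurement_raises(self):
        rows = [("s1", "ref", 1, 15.0), ("s1", "t", 1, 20.0), ("s2", "t", 1, 21.0)]
        with pytest.raises(InputError, match="reference"):
            xp.relative_expression_ddct(self._table(rows), "ref", "s1")


class TestPhenotypeComparison:
    def _meta(self, high, low):
        return pd.DataFrame(
            {
                "bnf_class": ["high"] * len(high) + ["low"] * len(low),
                "ethylene": list(high) + list(low),
            }
        )

    def test_identical_distributions_not_significant(self):
        rep = xp.compare_phenotype_groups(self._meta([1, 2, 3], [1, 2, 3]))
        assert rep["p_one_tailed"] >= 0.5

    def test_exact_enumeration_for_separated_groups(self):
        # high {4,5,6} vs low {1,2,3}: only 1 of C(6,3)=20 rank assignments is as extreme
        rep = xp.compare_phenotype_groups(self._meta([4, 5, 6], [1, 2, 3]))
        assert rep["method"] == "exact"
        assert rep["p_one_tailed"] == pytest.approx(1 / 20)

    def test_exact_matches_scipy_permutation_on_random_data(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(1, 1, 6), rng.normal(0, 1, 5)
        rep = xp.compare_phenotype_groups(self._meta(a, b))
        ref = stats.mannwhitneyu(a, b, alternative="greater", method="exact")
        assert rep["p_one_tailed"] == pytest.approx(ref.pvalue)

    def test_perfectly_linear_mass_gives_unit_r_squared(self):
        meta = self._meta([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        meta["ploidy"] = "2n"
        meta["fresh_mass"] = 100 + 50 * meta["ethylene"]
        rep = xp.compare_phenotype_groups(meta)
        assert rep["mass_regressions_by_ploidy"]["2n"]["r_squared"] == pytest.approx(1.0)
        assert rep["mass_regressions_by_ploidy"]["2n"]["slope"] == pytest.approx(50.0)

    def test_small_group_raises(self):
        with pytest.raises(InputError):
            xp.compare_phenotype_groups(self._meta([1.0], [2.0, 3.0]))
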