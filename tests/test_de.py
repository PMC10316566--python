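"""DE tests against independent oracles: exact rank-sum enumeration,
brute-force step-up adjustment, Poisson closed-form MLE, hand-computed
median-of-ratios, and parameter-recovery simulations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from degrecap.de import (
    DETestError,
    adjust_pvalues,
    call_degs,
    nb_wald_test,
    size_factors_median_of_ratios,
    wilcoxon_rank_sum,
)
from degrecap.io import CountMatrix
from degrecap.preprocess import NormalizedMatrix, log_normalize


# -- oracles -----------------------------------------------------------------


def bh_stepup_bruteforce(p):
    """Literal step-up definition: adj_(i) = min_{j>=i}(p_(j) * m / j), capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def exact_ranksum_pvalue(x, y):
    """Two-sided permutation p-value of the rank-sum statistic, full enumeration."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(x)].sum()
    mean = len(x) * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), len(x)):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def _norm_from_values(values, groups):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        genes=np.array([f"g{i}" for i in range(values.shape[0])], dtype=object),
        columns=np.array([f"c{j}" for j in range(values.shape[1])], dtype=object),
        values=values,
        column_groups=np.asarray(groups, dtype=object),
        column_library=np.asarray(["L"] * values.shape[1], dtype=object),
    )


# -- multiple-testing adjustment --------------------------------------------


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        adj = adjust_pvalues([0.01, 0.04, 0.03, 0.002], "bh")
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.008], rtol=1e-12)

    def test_single_pvalue_unchanged_under_bh(self):
        assert adjust_pvalues([0.3], "bh")[0] == pytest.approx(0.3)

    def test_bonferroni_caps_at_one(self):
        adj = adjust_pvalues([0.3, 0.01, 0.2, 0.5], "bonferroni")
        assert adj[0] == 1.0
        assert adj[1] == pytest.approx(0.04)

    def test_nan_excluded_from_m_and_propagated(self):
        adj = adjust_pvalues([0.01, np.nan, 0.04], "bonferroni")
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m = 2, not 3

    def test_out_of_range_rejected(self):
        with pytest.raises(DETestError):
            adjust_pvalues([0.5, 1.5], "bh")

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_bh_matches_stepup_bruteforce(self, p):
        np.testing.assert_allclose(
            adjust_pvalues(p, "bh"), bh_stepup_bruteforce(p), rtol=1e-10, atol=1e-12
        )

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_ordering_invariants(self, p):
        bh = adjust_pvalues(p, "bh")
        bonf = adjust_pvalues(p, "bonferroni")
        p = np.asarray(p)
        assert (bh >= p - 1e-12).all()
        assert (bonf >= bh - 1e-12).all()
        # BH never inverts the unadjusted ordering
        order = np.argsort(p, kind="stable")
        assert (np.diff(bh[order]) >= -1e-12).all()


class TestCallDegs:
    def test_threshold_is_inclusive(self):
        res = pd.DataFrame(
            {"gene_id": ["a", "b"], "p_bh": [0.05, 0.050001], "p_bonf": [1.0, 1.0]}
        )
        assert call_degs(res, 0.05, "bh") == {"a"}

    def test_empty_table(self):
        assert call_degs(pd.DataFrame(columns=["gene_id", "p_bh"])) == set()

    def test_alpha_one_takes_all_tested(self):
        res = pd.DataFrame({"gene_id": ["a", "b"], "p_bh": [0.9, np.nan]})
        assert call_degs(res, alpha=1.0) == {"a"}


# -- size factors ------------------------------------------------------------


class TestSizeFactors:
    def test_hand_computed_example(self):
        cm = CountMatrix(
            genes=["a", "b", "c"], columns=["s1", "s2"],
            counts=np.array([[2, 4], [6, 12], [10, 20]]),
        )
        sf = size_factors_median_of_ratios(cm)
        np.testing.assert_allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_exact_doubling_gives_proportional_factors(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(20, size=5) + 1
        cm = CountMatrix(
            genes=[f"g{i}" for i in range(5)], columns=["s1", "s2"],
            counts=np.column_stack([base, base * 2]),
        )
        sf = size_factors_median_of_ratios(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_identical_columns_equal_factors(self):
        cm = CountMatrix(
            genes=["a", "b"], columns=["s1", "s2", "s3"],
            counts=np.tile([[3], [9]], (1, 3)),
        )
        sf = size_factors_median_of_ratios(cm)
        np.testing.assert_allclose(sf.to_numpy(), 1.0, rtol=1e-12)

    def test_no_common_positive_gene_rejected(self):
        cm = CountMatrix(
            genes=["a", "b"], columns=["s1", "s2"],
            counts=np.array([[1, 0], [0, 1]]),
        )
        with pytest.raises(DETestError, match="cannot normalize"):
            size_factors_median_of_ratios(cm)


# -- NB Wald test ------------------------------------------------------------


def _two_group_cm(counts):
    counts = np.asarray(counts)
    n = counts.shape[1] // 2
    return CountMatrix(
        genes=[f"g{i}" for i in range(counts.shape[0])],
        columns=[f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
        column_groups=["A"] * n + ["B"] * (counts.shape[1] - n),
    )


class TestNbWaldTest:
    def test_poisson_closed_form_oracle(self):
        """At the dispersion floor with unit size factors the fit is the
        two-group Poisson MLE: coef = ln(S2/S1), SE = sqrt(1/S1 + 1/S2)."""
        rng = np.random.default_rng(3)
        counts = np.column_stack(
            [rng.poisson(100, size=50) for _ in range(3)]
            + [rng.poisson(220, size=50) for _ in range(3)]
        )
        cm = _two_group_cm(counts)
        sf = pd.Series(1.0, index=list(cm.columns))
        res = nb_wald_test(cm, size_factors=sf, dispersions=np.full(50, 1e-8))
        s1 = counts[:, :3].sum(axis=1)
        s2 = counts[:, 3:].sum(axis=1)
        np.testing.assert_allclose(
            res["log2fc"].to_numpy(), np.log(s2 / s1) / np.log(2), rtol=1e-5
        )
        se_oracle = np.sqrt(1 / s1 + 1 / s2)
        z_oracle = np.log(s2 / s1) / se_oracle
        np.testing.assert_allclose(res["stat"].to_numpy(), z_oracle, rtol=1e-4)

    def test_parameter_recovery_log2fc_two(self):
        """200 NB genes with true log2FC = 2 at base mean 100, 3 vs 3."""
        rng = np.random.default_rng(7)
        mu_a, alpha = 100.0, 0.05
        a = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu_a), size=(200, 3))
        b = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu_a * 4), size=(200, 3))
        res = nb_wald_test(
            _two_group_cm(np.column_stack([a, b])),
            size_factors=pd.Series(1.0, index=[f"s{j}" for j in range(6)]),
        )
        assert 1.8 <= res["log2fc"].mean() <= 2.2

    def test_null_log2fc_near_zero_with_large_counts(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(10_000, size=(100, 6))
        res = nb_wald_test(_two_group_cm(counts))
        assert abs(res["log2fc"].mean()) < 0.01
        # p-values roughly uniform: not over-enriched at the tail
        assert (res["p_unadj"] <= 0.05).mean() < 0.12

    def test_all_zero_gene_gets_na_and_excluded_from_m(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, size=(10, 6))
        counts[3] = 0
        res = nb_wald_test(_two_group_cm(counts))
        assert np.isnan(res.loc[3, "p_unadj"])
        m_used = (~res["p_unadj"].isna()).sum()
        np.testing.assert_allclose(
            res["p_bonf"].to_numpy()[:3],
            np.minimum(1.0, res["p_unadj"].to_numpy()[:3] * m_used),
        )

    def test_single_replicate_group_rejected(self):
        cm = CountMatrix(
            genes=["g"], columns=["s1", "s2", "s3"],
            counts=np.array([[5, 6, 7]]), column_groups=["A", "B", "B"],
        )
        with pytest.raises(DETestError, match="replication|2 columns"):
            nb_wald_test(cm)


# -- Wilcoxon rank-sum -------------------------------------------------------


class TestWilcoxon:
    def test_identical_multisets_give_p_one(self):
        vals = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        res = wilcoxon_rank_sum(_norm_from_values(vals, ["A"] * 3 + ["B"] * 3))
        assert res.loc[0, "p_unadj"] == pytest.approx(1.0, abs=0.05)
        assert res.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_constant_gene_p_one_by_convention(self):
        vals = np.array([[2.0, 2.0, 2.0, 2.0]])
        res = wilcoxon_rank_sum(_norm_from_values(vals, ["A", "A", "B", "B"]))
        assert res.loc[0, "p_unadj"] == 1.0

    def test_three_vs_three_matches_exact_enumeration(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        exact = exact_ranksum_pvalue(x, y)
        assert exact == pytest.approx(0.1)
        res = wilcoxon_rank_sum(
            _norm_from_values(np.concatenate([x, y])[None, :], ["A"] * 3 + ["B"] * 3)
        )
        assert abs(res.loc[0, "p_unadj"] - exact) <= 0.02

    @pytest.mark.parametrize("seed", range(6))
    def test_small_groups_match_enumeration_without_ties(self, seed):
        """Normal approximation within |dp| <= 0.02 of exact enumeration, n <= 8."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9), rng.integers(3, 9)
        vals = rng.normal(size=n1 + n2)
        exact = exact_ranksum_pvalue(vals[:n1], vals[n1:])
        res = wilcoxon_rank_sum(
            _norm_from_values(vals[None, :], ["A"] * int(n1) + ["B"] * int(n2))
        )
        assert abs(res.loc[0, "p_unadj"] - exact) <= 0.02

    def test_null_type_one_error_calibrated(self):
        """Empirical size at p <= 0.05 within 3 binomial SEs, 50 cells/group."""
        rng = np.random.default_rng(123)
        n_genes = 2000
        vals = rng.normal(size=(n_genes, 100))
        res = wilcoxon_rank_sum(_norm_from_values(vals, ["A"] * 50 + ["B"] * 50))
        frac = (res["p_unadj"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert frac <= 0.05 + 3 * se

    def test_log2fc_is_expm1_mean_ratio(self):
        cm = CountMatrix(
            genes=["g1", "g2"], columns=["c1", "c2"],
            counts=np.array([[9, 3], [1, 7]]), column_groups=["A", "B"],
        )
        norm = log_normalize(cm, scale_factor=10.0)
        res = wilcoxon_rank_sum(norm)
        dense = norm.dense()
        expected = np.log2(np.expm1(dense[:, 1]) + 1) - np.log2(np.expm1(dense[:, 0]) + 1)
        np.testing.assert_allclose(res["log2fc"].to_numpy(), expected, rtol=1e-10)

    def test_prefilters_mark_genes_untested(self):
        vals = np.array([[0.0, 0.0, 1.0, 2.0], [1.0, 2.0, 1.1, 2.2]])
        norm = _norm_from_values(vals, ["A", "A", "B", "B"])
        res = wilcoxon_rank_sum(norm, logfc_threshold=10.0)
        assert res["p_unadj"].isna().all()
        res2 = wilcoxon_rank_sum(norm)
        assert res2["p_unadj"].notna().all()


class TestAgainstEstablishedImplementation:
    def test_nb_wald_agrees_with_pydeseq2_on_simulated_bulk(self):
        """Dual-route check: the self-contained NB Wald test should closely
        track the reference DESeq2 implementation (pydeseq2) on replicate
        bulk counts — near-identical fold changes, strongly concordant
        p-value rankings and DEG calls."""
        from scipy.stats import spearmanr

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        from degrecap.simulate import SimulationConfig, simulate_paired_experiment

        cfg = SimulationConfig(
            n_genes=500, n_cells_per_type=100, frac_de=0.3,
            bulk_depth=1_000_000, seed=17,
        )
        exp = simulate_paired_experiment(cfg)
        mine = nb_wald_test(exp.bulk)

        counts = pd.DataFrame(
            exp.bulk.dense().T, index=list(exp.bulk.columns),
            columns=list(exp.bulk.genes),
        )
        meta = pd.DataFrame(
            {"condition": exp.bulk.column_groups}, index=list(exp.bulk.columns)
        )
        dds = DeseqDataSet(counts=counts, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "typeB", "typeA"], quiet=True)
        stats.summary()
        ref = stats.results_df

        merged = mine.set_index("gene_id").join(ref, how="inner", rsuffix="_ds")
        well_expressed = merged["baseMean"] > 5
        sub = merged[well_expressed]
        assert len(sub) > 400
        lfc_corr = np.corrcoef(sub["log2fc"], sub["log2FoldChange"])[0, 1]
        assert lfc_corr > 0.99
        rho = spearmanr(sub["p_unadj"], sub["pvalue"]).statistic
        assert rho > 0.9
        mine_degs = set(merged.index[merged["p_bh"] <= 0.05])
        ref_degs = set(merged.index[merged["padj"] <= 0.05])
        jaccard = len(mine_degs & ref_degs) / len(mine_degs | ref_degs)
        assert jaccard > 0.8
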