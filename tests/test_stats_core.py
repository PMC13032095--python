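import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import painsig as ps
from painsig.exceptions import ConfigurationError
from painsig.stats_core import midrank


class TestSpearman:
    def test_perfect_antitone(self):
        rho, p = ps.spearman([1, 2, 3], [3, 2, 1])
        assert rho == -1.0 and p == 0.0

    def test_tie_free_textbook_value(self):
        # 1 - 6 * sum(d^2) / (n (n^2 - 1)) with sum(d^2) = 2
        rho, _ = ps.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        if seed % 2:  # exercise tie handling
            x = np.round(x, 1)
        rho, p = ps.spearman(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)
        ref_rho, ref_p = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=1e-8)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 3.0, 5.0, np.nan, 7.0]
        rho, _ = ps.spearman(x, y)
        ref, _ = sps.spearmanr([1, 2, 4, 6], [2, 1, 5, 7])
        assert rho == pytest.approx(ref, abs=1e-12)

    def test_constant_vector_is_undefined_marker(self):
        rho, p = ps.spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert np.isnan(rho) and np.isnan(p)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho, _ = ps.spearman(x, y)
        rho2, _ = ps.spearman(np.exp(x), y**3)  # strictly monotone transforms
        assert rho == pytest.approx(rho2, abs=1e-12)


class TestBHFDR:
    def test_singleton_identity(self):
        assert ps.bh_fdr([0.05]) == pytest.approx([0.05])

    def test_step_up_minima(self):
        assert ps.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert ps.bh_fdr([0.04, 0.001]) == pytest.approx([0.04, 0.002])

    def test_empty_family(self):
        assert ps.bh_fdr([]).size == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=25)
        q = ps.bh_fdr(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)

    def test_exhaustive_small_families_against_definition(self):
        # brute-force step-up definition on every family of size <= 8 drawn
        # from a fixed grid of p values
        grid = [0.001, 0.02, 0.2, 0.9]
        rng = np.random.default_rng(3)
        for m in range(1, 9):
            for _ in range(20):
                p = rng.choice(grid, size=m)
                q = ps.bh_fdr(p)
                order = np.argsort(p, kind="mergesort")
                for rank_pos, i in enumerate(order):
                    brute = min(
                        min(m * p[j] / (list(order).index(j) + 1)
                            for j in order[rank_pos:]),
                        1.0,
                    )
                    assert q[i] == pytest.approx(brute, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_invariants(self, p):
        q = ps.bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)      # q >= p elementwise
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)     # nondecreasing along sorted p
        # reordering the family permutes q identically
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = ps.bh_fdr(np.asarray(p)[perm])
        assert np.allclose(np.sort(q_perm), np.sort(q))

    def test_nan_markers_excluded_from_family_size(self):
        q = ps.bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # m = 2, not 3


class TestPairedT:
    def test_textbook_example(self):
        t, df, _ = ps.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-9)
        assert df == 2

    def test_identical_vectors_zero_branch(self):
        with pytest.warns(UserWarning):
            t, df, p = ps.paired_t([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_infinite_marker(self):
        with pytest.warns(UserWarning):
            t, _, p = ps.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(t) and p == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.3
        t, df, p = ps.paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        assert df == 29


class TestWilcoxonRankSum:
    def test_small_sample_exact(self):
        res = ps.wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res["p_exact"] == pytest.approx(1.0 / 3.0)

    def test_identical_groups_z_zero(self):
        res = ps.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["z"] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_normal_approx_close_to_exact(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 6)
        res = ps.wilcoxon_rank_sum(a, b)
        assert abs(res["p"] - res["p_exact"]) < 0.02

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_mannwhitney(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.5, 1, 30)
        res = ps.wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res["p"] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ConfigurationError):
            ps.wilcoxon_rank_sum([], [1.0])


class TestRMANOVA:
    def test_two_conditions_epsilon_is_one(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(12, 2))
        res = ps.rm_anova_gg(data)
        assert res.eps_gg == pytest.approx(1.0)

    def test_toy_matrix_against_brute_force_decomposition(self):
        data = np.array([[1, 2, 3], [2, 3, 4], [1, 3, 5], [2, 4, 6]], dtype=float)
        n, k = data.shape
        # independent sums-of-squares oracle, spelled out
        grand = data.mean()
        ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
        resid = data - data.mean(axis=1)[:, None] - data.mean(axis=0) + grand
        ss_err = (resid**2).sum()
        f_ref = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        res = ps.rm_anova_gg(data)
        assert res.F == pytest.approx(f_ref, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pingouin(self, seed):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(seed)
        base = rng.normal(size=(15, 1))
        data = base + rng.normal(size=(15, 3)) + np.array([0.0, 0.4, 0.9])
        res = ps.rm_anova_gg(data)
        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "cond": np.tile(np.arange(3), 15),
                "subj": np.repeat(np.arange(15), 3),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                          correction=True)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), abs=1e-8)
        assert res.eps_gg == pytest.approx(float(ref["eps"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(ref["p_GG_corr"].iloc[0]), abs=1e-8)

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(7)
        subj = rng.normal(size=(4000, 1))
        data = subj + rng.normal(size=(4000, 3))  # exchangeable errors
        res = ps.rm_anova_gg(data)
        assert res.eps_gg == pytest.approx(1.0, abs=0.02)

    def test_invariance_to_subject_constant(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(10, 4))
        shifted = data + rng.normal(size=(10, 1)) * 5.0
        a, b = ps.rm_anova_gg(data), ps.rm_anova_gg(shifted)
        assert a.F == pytest.approx(b.F, abs=1e-9)

    def test_epsilon_bounds_asserted(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            data = rng.normal(size=(8, 4)) * np.array([1.0, 5.0, 0.2, 2.0])
            res = ps.rm_anova_gg(data)
            assert 1.0 / 3.0 - 1e-12 <= res.eps_gg <= 1.0 + 1e-12
            assert res.df1 == pytest.approx(3 * res.eps_gg)

    def test_degenerate_inputs(self):
        with pytest.raises(ConfigurationError):
            ps.rm_anova_gg(np.ones((5, 1)))
        with pytest.raises(ConfigurationError):
            ps.rm_anova_gg(np.ones((6, 3)))  # no within-subject variance


class TestShapiroWilk:
    def test_normal_scores_accepted(self):
        x = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, p = ps.shapiro_wilk(x)
        assert p > 0.5

    def test_skewed_sample_rejected(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=100)
            _, p = ps.shapiro_wilk(x)
            hits += p < 0.05
        assert hits >= 19

    def test_constant_vector_errors(self):
        with pytest.raises(ConfigurationError):
            ps.shapiro_wilk(np.ones(10))


class TestBattery:
    def test_family_structure_and_q_labels(self, small_cohort, protocol):
        cfg, profiles, traces, _ = small_cohort
        epoch, _ = ps.epoch_means_table(traces, protocol)
        idx = ps.build_profiles(epoch, protocol)
        traits = ps.traits_table(profiles)
        out = ps.correlation_battery(traits, idx, ["tai_46", "contrast_magnitude"])
        # 35 NEO + 4 attachment predictors per index
        assert len(out) == 2 * (35 + 4)
        for fam, sub in out.groupby("family"):
            assert len(sub) in (35, 4)
            valid = sub.dropna(subset=["q"])
            assert (valid["q"] >= valid["p"] - 1e-12).all()
        assert set(out["significance"]) <= {"significant", "trend", "ns", "undefined"}

    def test_attachment_domain_matrix_shape(self, small_cohort):
        cfg, profiles, _, _ = small_cohort
        out = ps.attachment_domain_matrix(ps.traits_table(profiles))
        assert len(out) == 20
        assert (out["q"] >= out["p"] - 1e-12).all()
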