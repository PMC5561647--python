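"""Poisson group-effect deviance test, BH adjustment, t-tests and log changes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flxsig import behavior as bhv
from flxsig import differential as diff
from flxsig import synthetic as syn
from flxsig.errors import ConfigurationError

GROUPS_576 = np.array(["CORT/V"] * 5 + ["Flx-R"] * 7 + ["Flx-NR"] * 6)


class TestPoissonGroupTest:
    def test_identical_counts_give_zero_deviance(self):
        y = np.full(18, 5.0)
        dev, p, df = diff.poisson_group_deviance(y, GROUPS_576)
        assert dev == 0.0 and p == 1.0 and df == 2

    def test_all_zero_row_is_degenerate(self):
        dev, p, _ = diff.poisson_group_deviance(np.zeros(18), GROUPS_576)
        assert (dev, p) == (0.0, 1.0)

    def test_two_group_closed_form_agreement(self):
        """Deviance equals 2*[S_a log(m_a/m) + S_b log(m_b/m)] for two groups."""
        rng = np.random.default_rng(5)
        y = rng.poisson([4] * 5 + [9] * 5).astype(float)
        g = np.array(["a"] * 5 + ["b"] * 5)
        dev, p, df = diff.poisson_group_deviance(y, g)
        sa, sb = y[:5].sum(), y[5:].sum()
        la, lb, l0 = sa / 5, sb / 5, y.mean()
        expected = 2 * (sa * np.log(la / l0) + sb * np.log(lb / l0))
        assert dev == pytest.approx(expected, abs=1e-10)
        assert df == 1

    def test_agrees_with_irls_glm_fit(self):
        """Closed-form deviance matches an independent iterative Poisson GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        y = rng.poisson([5] * 5 + [12] * 7 + [7] * 6).astype(float)
        x = pd.get_dummies(pd.Series(GROUPS_576), drop_first=True, dtype=float)
        full = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        null = sm.GLM(y, np.ones((18, 1)), family=sm.families.Poisson()).fit()
        lrt = 2 * (full.llf - null.llf)
        dev, _, _ = diff.poisson_group_deviance(y, GROUPS_576)
        assert dev == pytest.approx(lrt, abs=1e-8)

    def test_relabeling_within_groups_is_invariant(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(10, size=18).astype(float)
        _, p1, _ = diff.poisson_group_deviance(y, GROUPS_576)
        perm = np.r_[np.random.default_rng(0).permutation(5),
                     5 + np.random.default_rng(0).permutation(7),
                     12 + np.random.default_rng(0).permutation(6)]
        _, p2, _ = diff.poisson_group_deviance(y[perm], GROUPS_576)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_power_under_strong_effect(self):
        """Group means (2, 8, 2), n=5 each: rejection rate at p<0.05 above 0.95."""
        rng = np.random.default_rng(12)
        g = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        n_rej = 0
        reps = 1000
        rates = np.array([2.0] * 5 + [8.0] * 5 + [2.0] * 5)
        y = rng.poisson(rates, size=(reps, 15))
        counts = pd.DataFrame(y)
        design = diff.DesignSpec(sample_groups={i: g[i] for i in range(15)})
        res = diff.fit_group_poisson_matrix(counts, design)
        assert (res["p_group"] < 0.05).mean() > 0.95

    def test_matrix_path_matches_scalar_path(self):
        counts, groups, _ = syn.simulate_counts(syn.ProteomeSimConfig(n_proteins=30, seed=2))
        design = diff.DesignSpec(sample_groups=dict(groups))
        res = diff.fit_group_poisson_matrix(counts, design)
        garr = np.asarray([groups[s] for s in counts.columns])
        for acc in counts.index[:10]:
            dev, p, _ = diff.poisson_group_deviance(counts.loc[acc].to_numpy(), garr)
            assert res.loc[acc, "deviance"] == pytest.approx(dev, abs=1e-10)
            assert res.loc[acc, "p_group"] == pytest.approx(p, abs=1e-12)

    def test_offset_mode_absorbs_library_size(self):
        """Doubling one sample's library is no evidence of a group effect
        under total-count normalization."""
        counts = pd.DataFrame(
            np.vstack([np.full(6, 10), np.full(6, 20)]),
            columns=[f"s{i}" for i in range(6)],
        )
        counts["s0"] *= 2
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        raw = diff.fit_group_poisson_matrix(counts, diff.DesignSpec(sample_groups=groups))
        norm = diff.fit_group_poisson_matrix(
            counts, diff.DesignSpec(sample_groups=groups, normalization="total-count")
        )
        assert norm["deviance"].max() < 1e-10 < raw["deviance"].max()


class TestBH:
    def test_step_up_worked_example(self):
        q = diff.adjust_bh([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        assert np.allclose(diff.adjust_bh([1.0, 1.0, 1.0]), 1.0)
        assert diff.adjust_bh([0.037])[0] == pytest.approx(0.037)

    def test_order_preserved_and_q_at_least_p(self, rng):
        p = rng.uniform(size=50)
        q = diff.adjust_bh(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        # permuting inputs permutes outputs identically
        perm = rng.permutation(50)
        assert np.allclose(diff.adjust_bh(p[perm]), q[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigurationError):
            diff.adjust_bh([0.5, 1.5])


def permutation_ttest_p(a, b):
    """Exact enumeration oracle: two-sided pooled-t permutation p-value."""
    pooled = np.concatenate([a, b])
    n = len(a)
    t_obs = abs(stats.ttest_ind(a, b, equal_var=True).statistic)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        t = stats.ttest_ind(pooled[mask], pooled[~mask], equal_var=True).statistic
        count += abs(t) >= t_obs - 1e-12
        total += 1
    return count / total


class TestPairwiseTTest:
    def test_identical_sides_give_p_one(self):
        p, d = diff.pairwise_ttest([10, 10, 10], [10, 10, 10])
        assert (p, d) == (1.0, 0.0)

    def test_zero_variance_unequal_means_is_degenerate(self):
        p, d = diff.pairwise_ttest([5, 5, 5], [9, 9, 9])
        assert p == 0.0 and d == -4.0

    def test_matches_scipy_student(self, rng):
        a, b = rng.poisson(8, 6), rng.poisson(12, 5)
        p, d = diff.pairwise_ttest(a, b)
        assert p == pytest.approx(stats.ttest_ind(a, b, equal_var=True).pvalue)
        assert d == pytest.approx(a.mean() - b.mean())

    def test_close_to_exact_permutation_p(self):
        """Moderate-effect fixture: Student p tracks the exact permutation p."""
        a = np.array([8.0, 11.0, 9.0, 13.0])
        b = np.array([7.0, 6.0, 10.0, 8.0])
        p_t, _ = diff.pairwise_ttest(a, b)
        p_perm = permutation_ttest_p(a, b)
        assert abs(p_t - p_perm) < 0.06

    def test_strong_effect_fixture_agrees_in_significance(self):
        a = np.array([12.0, 15.0, 11.0, 14.0])
        b = np.array([5.0, 4.0, 6.0, 5.0])
        p_t, d = diff.pairwise_ttest(a, b)
        p_perm = permutation_ttest_p(a, b)
        assert d > 0
        assert p_t < 0.05 and p_perm <= 0.05
        assert abs(p_t - p_perm) < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            diff.pairwise_ttest([1.0], [2.0, 3.0])


class TestLogChange:
    def test_closed_form(self):
        row = np.array([7.0, 7.0, 3.0, 3.0])
        g = np.array([True, True, False, False])
        assert diff.log_change(row, g, ~g, 0.5) == pytest.approx(np.log2(7.5 / 3.5))

    def test_equal_means_give_zero_and_sign_is_correct(self):
        row = np.array([4.0, 4.0, 2.0, 2.0])
        g = np.array([True, True, False, False])
        assert diff.log_change(row, g, g) == 0.0
        assert diff.log_change(row, g, ~g) > 0

    def test_requires_positive_pseudocount(self):
        with pytest.raises(ConfigurationError):
            diff.log_change(np.ones(4), np.ones(4, bool), np.ones(4, bool), 0.0)


class TestRunDifferential:
    def test_full_table_shape_and_ranges(self, small_proteome):
        from flxsig import inference as inf

        _, psms, _, design = small_proteome
        filtered = inf.filter_identifications(psms)
        m = inf.build_count_matrix(filtered, inf.group_proteins(filtered), design)
        res = diff.run_differential(m)
        for col in ["p_group", "q_group", "p_R_vs_CORT", "p_NR_vs_CORT", "p_R_vs_NR"]:
            assert res[col].between(0, 1).all()
        assert (res["q_group"] >= res["p_group"] - 1e-12).all()
        assert np.isfinite(res[["delta_R", "delta_NR"]]).all().all()

    def test_equal_group_means_give_zero_deltas(self):
        counts = pd.DataFrame(
            [np.array([5] * 18)], index=["A"], columns=[f"s{i}" for i in range(18)]
        )
        groups = {f"s{i}": g for i, g in enumerate(GROUPS_576)}
        design = diff.DesignSpec(sample_groups=groups)
        from flxsig.inference import CountMatrix

        m = CountMatrix(counts=counts, sample_groups=pd.Series(groups), row_meta=pd.DataFrame(index=["A"]))
        out = diff.run_differential(m, design)
        assert out.loc["A", "delta_R"] == 0.0
        assert out.loc["A", "delta_NR"] == 0.0
        assert out.loc["A", "p_group"] == 1.0
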