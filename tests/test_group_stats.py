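"""ANOVA, pooled-t post-hocs, BKY two-stage FDR, Pearson correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hpcmri.group_stats import (
    FdrConfig,
    GroupData,
    bky_fdr,
    one_way_anova,
    pearson_corr,
    posthoc_pairwise,
    summarize_groups,
)


def _gd(*groups):
    return GroupData(
        labels=tuple(f"g{i}" for i in range(len(groups))),
        values=tuple(np.asarray(g, float) for g in groups),
    )


class TestAnova:
    def test_identical_observations_error(self):
        with pytest.raises(ValueError, match="undefined"):
            one_way_anova(_gd([1.0, 1.0], [1.0, 1.0]))

    def test_equal_means_with_spread_give_zero_f(self):
        f, p = one_way_anova(_gd([1.0, 3.0], [0.0, 4.0], [1.5, 2.5]))
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        f, p_f = one_way_anova(_gd(a, b))
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            one_way_anova(_gd([1.0, 2.0], [3.0]))

    def test_null_rejection_rate_calibrated(self):
        # 3 groups of n = 8 under the null; alpha = 0.05
        rng = np.random.default_rng(2024)
        n_rep, k, n = 10_000, 3, 8
        x = rng.normal(size=(n_rep, k, n))
        means = x.mean(axis=2)
        grand = x.mean(axis=(1, 2))
        ssb = n * ((means - grand[:, None]) ** 2).sum(axis=1)
        ssw = ((x - means[:, :, None]) ** 2).sum(axis=(1, 2))
        f = (ssb / (k - 1)) / (ssw / (k * n - k))
        pvals = sps.f.sf(f, k - 1, k * n - k)
        rate = np.mean(pvals < 0.05)
        assert 0.045 <= rate <= 0.055
        # spot-check the vectorized null against the implementation
        f0, p0 = one_way_anova(_gd(*x[0]))
        assert f0 == pytest.approx(f[0], rel=1e-10)


class TestPosthoc:
    def test_identical_groups_give_p_near_one(self):
        p = posthoc_pairwise(_gd([1.0, 3.0], [0.0, 4.0]))
        assert p[("g0", "g1")] > 0.99

    def test_two_groups_match_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 7)
        p = posthoc_pairwise(_gd(a, b))[("g0", "g1")]
        assert p == pytest.approx(sps.ttest_ind(a, b, equal_var=True).pvalue, rel=1e-10)

    def test_overwhelming_separation(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(10, 1, 8)
        assert posthoc_pairwise(_gd(a, b))[("g0", "g1")] < 1e-6

    def test_welch_option_differs_under_heteroscedasticity(self, rng):
        a, b = rng.normal(0, 0.1, 8), rng.normal(0.5, 3.0, 8)
        pooled = posthoc_pairwise(_gd(a, b))[("g0", "g1")]
        welch = posthoc_pairwise(_gd(a, b), welch=True)[("g0", "g1")]
        assert pooled != welch


class TestBkyFdr:
    def test_all_ones_reject_nothing(self):
        reject, diag = bky_fdr([1.0, 1.0, 1.0])
        assert not reject.any()
        assert diag["r1"] == 0

    def test_single_pvalue_hand_case(self):
        # stage 1 at q' = 0.05/1.05 = 0.047619 rejects p = 0.04 -> reject all
        reject, diag = bky_fdr([0.04], FdrConfig(q=0.05))
        assert reject.tolist() == [True]
        assert diag["q_stage1"] == pytest.approx(0.047619, abs=1e-6)

    def test_three_pvalue_hand_case(self):
        # stage 1 rejects {0.010, 0.020}; m0_hat = 1; stage 2 at 0.15
        # rejects the same two and not 0.200
        reject, diag = bky_fdr([0.010, 0.020, 0.200], FdrConfig(q=0.05))
        assert reject.tolist() == [True, True, False]
        assert diag["r1"] == 2
        assert diag["m0_hat"] == 1
        assert diag["q_stage2"] == pytest.approx(0.15)

    def test_all_rejected_shortcut(self):
        reject, diag = bky_fdr([1e-5, 1e-6, 1e-4])
        assert reject.all()
        assert diag["r1"] == diag["m"]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bky_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bky_fdr([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_matches_reference_implementation(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours, _ = bky_fdr(pvals, FdrConfig(q=0.05))
        ref = multipletests(pvals, alpha=0.05, method="fdr_tsbky")[0]
        np.testing.assert_array_equal(ours, np.asarray(ref, bool))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=15))
    def test_superset_of_bh_and_monotone(self, pvals):
        from hpcmri.group_stats import _bh_stepup

        p = np.asarray(pvals)
        ours, _ = bky_fdr(p, FdrConfig(q=0.05))
        bh = _bh_stepup(p, 0.05 / 1.05)
        assert np.all(ours | ~bh)  # BKY rejects a superset of stage-1 BH
        if ours.any():
            p_max = p[ours].max()
            assert np.all(ours[p <= p_max])  # rejecting p_i implies all p_j <= p_i

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(7)
        m, reps, q = 10, 4000, 0.05
        fdp = np.empty(reps)
        for i in range(reps):
            reject, _ = bky_fdr(rng.uniform(size=m), FdrConfig(q=q))
            fdp[i] = reject.sum() / max(reject.sum(), 1) if reject.any() else 0.0
        fdr = fdp.mean()  # complete null: every rejection is false
        se = fdp.std(ddof=1) / np.sqrt(reps)
        assert fdr <= q + 2 * se


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_four_point_hand_value(self):
        # deviations (-1.5,-.5,.5,1.5) and (-.5,-1.5,1.5,.5): cov 3, var 5 each
        r, _ = pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 2.0], [1.0, 2.0])


class TestSummaries:
    def test_degenerate_groups(self):
        df = summarize_groups(_gd([1.0, 1.0, 1.0], [0.0, 2.0]))
        row0 = df[df.group == "g0"].iloc[0]
        assert row0["mean"] == 1.0 and row0["sem"] == 0.0
        row1 = df[df.group == "g1"].iloc[0]
        assert row1["mean"] == 1.0 and row1["sem"] == pytest.approx(1.0)

    def test_sem_estimates_parent_scale(self):
        # n = 8 draws with SD = 0.25*sqrt(8): SEM estimates center on 0.25
        rng = np.random.default_rng(99)
        n, sd = 8, 0.25 * np.sqrt(8)
        draws = rng.normal(2.70, sd, size=(10_000, n))
        sems = draws.std(axis=1, ddof=1) / np.sqrt(n)
        # E[sample SD] = sd * c4(8); allow the known small-sample bias
        assert np.mean(sems) == pytest.approx(0.25, rel=0.05)
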