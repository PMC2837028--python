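"""Pilot-data permutation estimator: relabelings, statistics, search."""

import math

import numpy as np
import pytest
from scipy import stats

from arraypower import (
    DataError,
    PermutationSampleSize,
    PilotDataset,
    StudyDesign,
    adjustment_factors,
    build_ensemble,
    build_shifted_statistics,
    count_detected,
    enumerate_relabelings,
    estimate_sample_size,
    gene_t_statistics,
    generate_pilot,
    null_critical_values,
    sample_size_confidence,
)


class TestEnumerateRelabelings:
    @pytest.mark.parametrize("n0p,n1p,expected", [(4, 4, 70), (3, 3, 20), (4, 6, 210)])
    def test_counts(self, n0p, n1p, expected):
        assigns = enumerate_relabelings(n0p, n1p)
        assert len(assigns) == math.comb(n0p + n1p, n0p)
        assert len(assigns) == expected
        assert len(set(assigns)) == expected

    def test_original_labeling_first(self):
        assert enumerate_relabelings(4, 4)[0] == (0, 1, 2, 3)

    def test_cap_enforced(self):
        with pytest.raises(DataError, match="Monte-Carlo"):
            enumerate_relabelings(11, 11)

    def test_complementary_assignments_negate_t(self, rng):
        values = rng.standard_normal((10, 8))
        t_a, _ = gene_t_statistics(values, [0, 1, 2, 3])
        t_b, _ = gene_t_statistics(values, [4, 5, 6, 7])
        np.testing.assert_allclose(t_a, -t_b, rtol=1e-12)


class TestGeneTStatistics:
    def test_matches_scipy_ttest(self, rng):
        values = rng.standard_normal((50, 8))
        t, sd = gene_t_statistics(values, [0, 1, 2, 3])
        ref = stats.ttest_ind(values[:, 4:], values[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-12)

    def test_hand_computed_fixture(self):
        # 2 genes, 3+3 samples; pooled sd and t worked out by hand
        values = np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [0.0, 0.0, 1.0, 1.0, 1.0, 2.0],
        ])
        t, sd = gene_t_statistics(values, [0, 1, 2])
        # gene 0: means 2 and 5, SS = 2 + 2, sd = 1, t = 3/sqrt(2/3)
        assert t[0] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert sd[0] == pytest.approx(1.0, rel=1e-12)
        # gene 1: means 1/3 and 4/3, SS = 2/3 + 2/3, sd = sqrt(1/3)
        assert sd[1] == pytest.approx(np.sqrt(1.0 / 3.0), rel=1e-12)
        assert t[1] == pytest.approx(1.0 / (np.sqrt(1.0 / 3.0) * np.sqrt(2.0 / 3.0)), rel=1e-12)

    def test_identical_group_means_give_zero(self):
        values = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        t, _ = gene_t_statistics(values, [0, 1, 2])
        assert t[0] == pytest.approx(0.0, abs=1e-15)

    def test_mean_over_all_relabelings_is_zero(self, rng):
        values = rng.standard_normal((5, 6))
        ts = [gene_t_statistics(values, a)[0] for a in enumerate_relabelings(3, 3)]
        np.testing.assert_allclose(np.mean(ts, axis=0), 0.0, atol=1e-12)

    def test_zero_variance_row_raises(self):
        values = np.vstack([np.ones(8), np.arange(8.0)])
        with pytest.raises(DataError, match="zero pooled variance"):
            gene_t_statistics(values, [0, 1, 2, 3])


class TestAdjustmentFactors:
    def test_printed_reference_values(self):
        # n = 13, pilot 4 + 4, alpha = 0.00249
        af = adjustment_factors(13, 4, 4, 0.00249)
        assert af.f1 == pytest.approx(0.6777, abs=5e-4)
        assert af.f2 == pytest.approx(1.155, abs=5e-4)
        assert af.f == pytest.approx(af.f1 * af.f2)

    def test_f1_unity_when_dfs_match(self):
        # 2n - 2 == n0p + n1p - 2  =>  identical quantiles
        af = adjustment_factors(4, 4, 4, 0.01)
        assert af.f1 == pytest.approx(1.0, rel=1e-12)

    def test_both_factors_converge_to_one(self):
        # pilot size approaching the target size: 2n-2 vs n0p+n1p-2 dfs align
        af = adjustment_factors(500, 500, 500, 0.001)
        assert af.f1 == pytest.approx(1.0, abs=5e-3)
        assert af.f2 == pytest.approx(1.0, abs=2e-3)

    def test_tiny_pilot_rejected(self):
        with pytest.raises(DataError):
            adjustment_factors(10, 1, 1, 0.01)


class TestNullCriticalValues:
    def test_tiny_hand_pool_nearest_rank(self):
        # sorted pool (-3,-1,0,1,3), alpha=0.4: ranks ceil(1) = 1, ceil(4) = 4
        lo, hi = null_critical_values(np.array([-3.0, -1.0, 0.0, 1.0, 3.0]), 0.4)
        assert (lo, hi) == (-3.0, 1.0)

    def test_small_pool_warns_when_quantile_unresolved(self):
        with pytest.warns(UserWarning, match="poorly resolves"):
            null_critical_values(np.arange(10.0), 0.05)

    def test_symmetric_pool_gives_symmetric_bounds(self, rng):
        pool = rng.standard_normal(5000)
        pool = np.concatenate([pool, -pool])
        lo, hi = null_critical_values(pool, 0.05)
        # symmetric up to one order statistic of rank granularity
        assert lo == pytest.approx(-hi, abs=0.02)

    def test_large_sample_normal_quantiles(self, rng):
        pool = rng.standard_normal(400_000)
        lo, hi = null_critical_values(pool, 0.05)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)


class TestCountDetected:
    def test_brute_force_agreement(self, rng):
        s = rng.standard_normal(20) * 3
        lo, hi = -2.0, 2.0
        assert count_detected(s, lo, hi) == sum(1 for v in s if v < lo or v > hi)

    def test_all_inside_none_detected(self):
        assert count_detected(np.zeros(10), -1.0, 1.0) == 0

    def test_degenerate_bounds_reject_everything(self):
        s = np.array([-1.0, 1.0, 2.0])
        assert count_detected(s, 0.0, 0.0) == 3


class TestPilotDataset:
    def test_group_sizes_and_ordering(self, small_pilot):
        assert small_pilot.n0p == 4 and small_pilot.n1p == 4
        assert small_pilot.m == 200

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError, match="at least 3"):
            PilotDataset(values=np.random.default_rng(0).standard_normal((5, 5)),
                         gene_ids=list("abcde"),
                         group_labels=["c", "c", "t", "t", "t"])

    def test_small_group_warns(self):
        with pytest.warns(UserWarning, match="recommended"):
            PilotDataset(values=np.random.default_rng(0).standard_normal((5, 7)),
                         gene_ids=list("abcde"),
                         group_labels=["c"] * 3 + ["t"] * 4)

    def test_constant_row_rejected_or_dropped(self):
        vals = np.random.default_rng(0).standard_normal((5, 8))
        vals[2] = 7.0
        ids = list("abcde")
        labels = ["c"] * 4 + ["t"] * 4
        with pytest.raises(DataError, match="zero variance"):
            PilotDataset(values=vals, gene_ids=ids, group_labels=labels)
        with pytest.warns(UserWarning, match="dropping"):
            pd_ = PilotDataset(values=vals.copy(), gene_ids=ids[:], group_labels=labels,
                               drop_degenerate=True)
        assert pd_.m == 4
        assert "c" not in pd_.gene_ids


class TestShiftedStatistics:
    def test_zero_effect_with_unit_factor_is_identity(self, small_pilot):
        ens = build_ensemble(small_pilot)
        # delta must be > 0 by design contract; use a vanishingly small one
        design = StudyDesign(m=200, m1=10, effect_sizes=1e-12, fdr_target=0.05,
                             sensitivity_target=0.7)
        build_shifted_statistics(ens, 1.0, design, 2, np.random.default_rng(0))
        b = 3
        alt = ens.alt_index_sets[b]
        np.testing.assert_allclose(ens.s1[b], ens.t[b][alt], atol=1e-9)

    def test_shift_magnitude_scales_with_target_size(self, small_pilot):
        ens = build_ensemble(small_pilot)
        design = StudyDesign(m=200, m1=10, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        build_shifted_statistics(ens, 1.0, design, 13, np.random.default_rng(0))
        b = 0
        alt = ens.alt_index_sets[b]
        shift = ens.s1[b] - ens.t[b][alt]
        expected = 2.0 * np.sqrt(13 / 2) / ens.sd_original[alt]
        np.testing.assert_allclose(shift, expected, rtol=1e-12)

    def test_seeded_reproducibility(self, small_pilot):
        design = StudyDesign(m=200, m1=10, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        outs = []
        for _ in range(2):
            ens = build_ensemble(small_pilot)
            build_shifted_statistics(ens, 0.8, design, 10, np.random.default_rng(99))
            outs.append((ens.alt_index_sets.copy(), ens.s1.copy()))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        np.testing.assert_array_equal(outs[0][1], outs[1][1])

    def test_alt_sets_have_m1_distinct_members(self, small_pilot):
        ens = build_ensemble(small_pilot)
        design = StudyDesign(m=200, m1=10, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        build_shifted_statistics(ens, 1.0, design, 10, np.random.default_rng(1))
        for row in ens.alt_index_sets:
            assert len(set(row.tolist())) == 10


class TestEstimateSampleSize:
    def test_search_starts_at_binomial_solution(self, small_pilot):
        design = StudyDesign(m=200, m1=10, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        res = estimate_sample_size(small_pilot, design, rng_seed=3)
        assert res.n_initial == sample_size_confidence(design).n
        assert res.n >= res.n_initial
        assert res.method == "confidence_permutation"
        assert res.achieved_confidence >= design.sensitivity_target

    def test_fixed_seed_reproduces_trace_bitwise(self, small_pilot):
        design = StudyDesign(m=200, m1=10, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        r1 = estimate_sample_size(small_pilot, design, rng_seed=11)
        r2 = estimate_sample_size(small_pilot, design, rng_seed=11)
        assert r1.n == r2.n and r1.trace == r2.trace and r1.f_trace == r2.f_trace

    def test_huge_effect_accepts_initial_candidate(self, small_pilot):
        design = StudyDesign(m=200, m1=10, effect_sizes=60.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        res = estimate_sample_size(small_pilot, design, rng_seed=5)
        assert res.n == res.n_initial
        assert res.trace[0][1] == design.m1  # u* saturates at m1 immediately

    def test_ensemble_replicate_count_and_u_bounds(self, small_pilot):
        design = StudyDesign(m=200, m1=10, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        res = estimate_sample_size(small_pilot, design, rng_seed=3)
        assert all(0 <= u <= design.m1 for _, u in res.trace)
        ens = build_ensemble(small_pilot)
        assert ens.N == math.comb(8, 4)

    def test_unadjusted_mode_overestimates_small_pilot(self):
        # pilot far smaller than the target: the f = 1 recipe inflates
        # the permutation null and so demands more arrays
        design = StudyDesign(m=500, m1=25, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        diffs = []
        for seed in range(4):
            pilot = generate_pilot(m=500, m1=25, delta0=2.0, n0p=4, n1p=4, rng_seed=100 + seed)
            adj = estimate_sample_size(pilot, design, mode="adjusted", rng_seed=seed)
            unadj = estimate_sample_size(pilot, design, mode="unadjusted", rng_seed=seed)
            assert unadj.method == "confidence_permutation_unadjusted"
            diffs.append(unadj.n - adj.n)
        assert np.mean(diffs) > 0

    def test_monte_carlo_fallback_for_large_pilots(self):
        design = StudyDesign(m=150, m1=8, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        pilot = generate_pilot(m=150, m1=8, delta0=2.0, n0p=11, n1p=11, rng_seed=0)
        model = PermutationSampleSize(pilot, design, max_relabelings=300)
        res = model.fit(seed=2)
        assert res.monte_carlo_relabelings
        assert res.n >= res.n_initial

    def test_design_pilot_size_mismatch_rejected(self, small_pilot):
        design = StudyDesign(m=2000, m1=100, effect_sizes=2.0, fdr_target=0.05,
                             sensitivity_target=0.7)
        with pytest.raises(DataError, match="gene count"):
            PermutationSampleSize(small_pilot, design)
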