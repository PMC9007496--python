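"""Thompson-Tau screen and two-sample t-tests against hand oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kymotrace as kt
from kymotrace.stats import tau_critical


class TestThompsonTau:
    def test_zero_sd_guard(self):
        res = kt.thompson_tau_screen([5.0, 5.0, 5.0, 5.0])
        assert res.removed.size == 0
        assert np.array_equal(res.retained, [5.0, 5.0, 5.0, 5.0])

    def test_hand_computed_outlier(self):
        # n=5: t_{0.025,3}=3.182 -> tau=1.571; s=43.62, cutoff 68.5 < |100-22|
        res = kt.thompson_tau_screen([1.0, 2.0, 3.0, 4.0, 100.0], alpha=0.05)
        assert list(res.removed) == [100.0]
        assert tau_critical(5, 0.05) == pytest.approx(1.571, abs=0.001)
        assert res.tau_thresholds[0] == pytest.approx(1.5712 * 43.6177, rel=1e-3)
        assert sorted(res.retained) == [1.0, 2.0, 3.0, 4.0]

    def test_idempotence_on_retained_set(self):
        rng = np.random.default_rng(0)
        data = np.append(rng.normal(0, 1, 19), 25.0)
        first = kt.thompson_tau_screen(data)
        second = kt.thompson_tau_screen(first.retained)
        assert second.removed.size == 0
        assert np.array_equal(second.retained, first.retained)

    def test_injected_outlier_always_removed(self):
        # a 10-sigma point in a clean n=20 normal sample must always go
        misses = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            data = np.append(rng.normal(0.0, 1.0, 19), 10.0)
            if 10.0 not in kt.thompson_tau_screen(data).removed:
                misses += 1
        assert misses == 0

    def test_clean_sample_removal_matches_theory(self):
        # the tau cutoff at n=20 (1.885) sits below the typical max
        # studentized deviation of a clean normal sample, so the screen is
        # aggressive by construction: a direct Monte-Carlo of
        # max|x - mean|/s over 20k samples gives P(>=1 removal) = 0.776 and
        # ~10% of points removed by the full iterative screen
        samples_hit = 0
        points_removed = 0
        for seed in range(500):
            rng = np.random.default_rng(10_000 + seed)
            res = kt.thompson_tau_screen(rng.normal(0.0, 1.0, 20))
            samples_hit += res.removed.size > 0
            points_removed += res.removed.size
        assert samples_hit / 500 == pytest.approx(0.776, abs=0.06)
        assert points_removed / (500 * 20) == pytest.approx(0.10, abs=0.03)

    def test_multiset_partition_and_tie_rule(self):
        data = [0.0, 0.1, -0.1, 10.0, -10.0, 0.05]
        res = kt.thompson_tau_screen(data)
        assert sorted(np.concatenate([res.retained, res.removed])) == sorted(data)
        if res.removed.size >= 1:
            # symmetric tie at max deviation: the larger value leaves first
            assert res.removed[0] == 10.0

    def test_sample_size_guard(self):
        with pytest.raises(kt.SampleSizeError):
            kt.thompson_tau_screen([1.0, 2.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_retained_plus_removed_is_input(self, values):
        res = kt.thompson_tau_screen(values)
        assert sorted(np.concatenate([res.retained, res.removed])) == pytest.approx(
            sorted(values)
        )
        assert res.removed.size <= len(values) - 2


class TestTTests:
    def test_identical_groups(self):
        res = kt.t_test_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_shifted_groups_hand_pooled(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        res = kt.t_test_two_tailed(a, b, variant="pooled")
        # pooled sd = 1, se = sqrt(2/3): t = -10 / 0.8165
        assert res.t_statistic == pytest.approx(-10.0 / math.sqrt(2.0 / 3.0), rel=1e-9)
        assert res.p_value < 0.001
        assert res.degrees_of_freedom == 4

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 3.0, 4.0, 5.0]
        pooled = kt.t_test_two_tailed(a, b, variant="pooled")
        welch = kt.t_test_two_tailed(a, b, variant="welch")
        assert pooled.t_statistic == pytest.approx(welch.t_statistic, rel=1e-12)
        assert pooled.p_value == pytest.approx(welch.p_value, rel=1e-9)

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1.2, 10)
        fwd = kt.t_test_two_tailed(a, b)
        rev = kt.t_test_two_tailed(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic, rel=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)

    def test_degenerate_zero_variance(self):
        res = kt.t_test_two_tailed([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        res = kt.t_test_two_tailed([2.0, 2.0], [3.0, 3.0])
        assert res.p_value == 0.0

    def test_raw_equals_summary(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(5, 2, 12), rng.normal(6, 3, 9)
        for variant in ("pooled", "welch"):
            raw = kt.t_test_two_tailed(a, b, variant=variant)
            (n1, m1, s1), (n2, m2, s2) = raw.group_summaries
            summ = kt.t_test_from_summary(n1, m1, s1, n2, m2, s2, variant=variant)
            assert raw.t_statistic == pytest.approx(summ.t_statistic, abs=1e-9)
            assert raw.p_value == pytest.approx(summ.p_value, abs=1e-9)
            assert raw.degrees_of_freedom == pytest.approx(
                summ.degrees_of_freedom, abs=1e-9
            )

    def test_published_fluorescence_summary_not_significant(self):
        # mean GLR-1::mCherry neurite fluorescence of the two reporter
        # strains: 470.4 ± 66.1 (n=15) vs 465.6 ± 68.2 (n=11), SEM
        res = kt.t_test_from_summary(15, 470.4, 66.1, 11, 465.6, 68.2)
        assert res.p_value > 0.9

    def test_doubling_sems_halves_t(self):
        r1 = kt.t_test_from_summary(10, 5.0, 1.0, 10, 4.0, 1.5)
        r2 = kt.t_test_from_summary(10, 5.0, 2.0, 10, 4.0, 3.0)
        assert r2.t_statistic == pytest.approx(r1.t_statistic / 2.0, rel=1e-12)
        assert r2.p_value > r1.p_value

    def test_sample_size_guards(self):
        with pytest.raises(kt.SampleSizeError):
            kt.t_test_two_tailed([1.0], [1.0, 2.0])
        with pytest.raises(kt.SampleSizeError):
            kt.t_test_from_summary(1, 0.0, 1.0, 5, 0.0, 1.0)
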