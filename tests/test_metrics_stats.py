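"""Trial metrics, DTW, and the statistical battery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fishnav.arena import ArenaConfig, Environment
from fishnav.metrics_stats import (
    Trajectory,
    TrialResult,
    anova_eta2,
    bootstrap_ci,
    bootstrap_success,
    cohens_d,
    collision_rate,
    distance_norm,
    dtw_distance,
    holm_bonferroni,
    power_analysis,
    time_to_target_norm,
    total_score,
    welch_ttest,
)


def brute_force_dtw(a, b):
    """Oracle: enumerate all monotone warping paths on tiny inputs."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    n, m = len(a), len(b)
    best = [np.inf]

    def rec(i, j, cost):
        cost += np.linalg.norm(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                rec(ni, nj, cost)

    rec(0, 0, 0.0)
    return best[0]


class TestNormalizedMetrics:
    def test_time_endpoints(self):
        assert time_to_target_norm(10.0, 5.0) == 0.0  # t_min = 5/0.5 = 10
        assert time_to_target_norm(45.0, 5.0) == 1.0
        assert time_to_target_norm(25.0, 2.5) == pytest.approx(0.5)

    def test_distance_endpoints(self):
        assert distance_norm(5.0, 5.0) == 0.0
        assert distance_norm(22.5, 0.0) == 1.0
        assert distance_norm(12.5, 2.5) == pytest.approx(0.5)

    def test_collision_counting_oracle(self):
        env = Environment(
            config=ArenaConfig(n_corals=1),
            coral_centers=np.array([[0.0, 0.0]]),
            start=np.array([-1.0, -1.0]),
            target=np.array([1.0, 1.0]),
        )
        xy = np.full((12, 2), 1.0)
        xy[:3] = 0.0  # 3 of 12 samples at the coral center
        traj = Trajectory(t=np.arange(12.0), xy=xy)
        assert collision_rate(traj, env) == pytest.approx(0.25)

    def test_total_score_examples(self):
        perfect = TrialResult(1, 0.0, 0.0, 0.0)
        assert total_score(perfect) == 1.0
        failed = TrialResult(0, None, None, 0.0)
        assert total_score(failed) == 0.0
        mixed = TrialResult(1, 0.25, 0.1, 0.05)
        assert total_score(mixed) == pytest.approx(0.8667, abs=1e-4)

    def test_total_score_bounds_and_monotonicity(self):
        """Score stays in [0,1] and decreases in each component over
        10,000 random inputs."""
        rng = np.random.default_rng(0)
        comp = rng.uniform(0, 1, size=(10_000, 3))
        scores = np.array(
            [total_score(TrialResult(1, *row)) for row in comp]
        )
        assert np.all((scores >= 0) & (scores <= 1))
        bumped = comp.copy()
        bumped[:, 0] = np.minimum(comp[:, 0] + 0.1, 1.0)
        scores_b = np.array(
            [total_score(TrialResult(1, *row)) for row in bumped]
        )
        assert np.all(scores_b <= scores + 1e-12)


class TestDTW:
    def test_identical_is_zero(self):
        a = np.random.default_rng(0).normal(size=(20, 2))
        assert dtw_distance(a, a) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(15, 2)), rng.normal(size=(15, 2))
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_three_point_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = rng.normal(size=(3, 2))
            b = rng.normal(size=(3, 2))
            assert dtw_distance(a, b) == pytest.approx(brute_force_dtw(a, b))

    def test_longer_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=(5, 2))
            b = rng.normal(size=(6, 2))
            # resampling stretches the shorter one first, as dtw_distance does
            from fishnav.metrics_stats import resample_trajectory

            a6 = resample_trajectory(a, 6)
            assert dtw_distance(a, b) == pytest.approx(brute_force_dtw(a6, b))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_pseudo_metric_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 2))
        b = rng.normal(size=(8, 2))
        assert dtw_distance(a, b) >= 0.0


class TestPowerAnalysis:
    def test_pair_counts(self):
        rng = np.random.default_rng(0)
        trajs = [rng.normal(size=(50, 2)) for _ in range(10)]
        assert len(power_analysis(trajs)) == 45
        assert len(power_analysis(trajs[:2])) == 1

    def test_identical_trajectories_all_zero(self):
        t = np.random.default_rng(1).normal(size=(30, 2))
        out = power_analysis([t.copy() for _ in range(5)])
        assert np.allclose(out, 0.0)


class TestStatistics:
    def test_bootstrap_success_degenerate(self):
        m, se = bootstrap_success(np.ones(30), seed=0)
        assert m == 1.0 and se == 0.0
        m, se = bootstrap_success(np.zeros(30), seed=0)
        assert m == 0.0 and se == 0.0

    def test_bootstrap_success_binomial_closed_form(self):
        flags = np.array([1.0] * 25 + [0.0] * 25)
        _, se = bootstrap_success(flags, n_boot=2000, seed=0)
        assert se == pytest.approx(np.sqrt(0.25 / 50), rel=0.2)

    def test_cohens_d_identity_and_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        assert cohens_d(a, a.copy()) == 0.0
        b = a + a.std(ddof=1)
        assert cohens_d(b, a) == pytest.approx(1.0, rel=1e-6)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_eta2_degenerate_cases(self):
        same = [np.array([1.0, 2.0, 3.0])] * 3
        assert anova_eta2(same) == 0.0
        distinct = [np.full(4, v) for v in (1.0, 2.0, 3.0)]
        assert anova_eta2(distinct) == 1.0

    def test_eta2_sum_of_squares_oracle(self):
        groups = [
            np.array([1.0, 2.0, 3.0]),
            np.array([2.0, 4.0]),
            np.array([5.0, 6.0, 7.0, 8.0]),
        ]
        allv = np.concatenate(groups)
        ss_tot = ((allv - allv.mean()) ** 2).sum()
        ss_err = sum(((g - g.mean()) ** 2).sum() for g in groups)
        expected = (ss_tot - ss_err) / ss_tot
        assert anova_eta2(groups) == pytest.approx(expected)

    def test_holm_single_and_stepdown(self):
        assert holm_bonferroni([0.04]) == [True]
        # (0.01, 0.04): first tested at alpha/2 = 0.025 -> reject; second at
        # alpha -> reject
        assert list(holm_bonferroni([0.01, 0.04])) == [True, True]
        # (0.03, 0.04): 0.03 > 0.025 -> neither rejected
        assert list(holm_bonferroni([0.03, 0.04])) == [False, False]
        assert not any(holm_bonferroni([1.0, 1.0, 1.0]))

    def test_bootstrap_ci_constant_and_coverage(self):
        lo, hi = bootstrap_ci(np.mean, np.full(50, 3.3), n=200, seed=0)
        assert lo == pytest.approx(3.3) and hi == pytest.approx(3.3)
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        lo, hi = bootstrap_ci(np.mean, x, n=2000, seed=2)
        assert lo <= x.mean() <= hi
        width_analytic = 2 * 1.96 * x.std(ddof=1) / np.sqrt(len(x))
        assert (hi - lo) == pytest.approx(width_analytic, rel=0.2)

    def test_welch_matches_reference_table(self):
        # printed toy dataset, reference values from scipy's implementation
        a = np.array([2.1, 2.5, 2.3, 2.9, 2.7])
        b = np.array([3.1, 3.3, 2.8, 3.6])
        t, p = welch_ttest(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert p < 0.05

    def test_trajectory_requires_increasing_time(self):
        with pytest.raises(ValueError):
            Trajectory(t=[0.0, 0.0], xy=np.zeros((2, 2)))
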