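import numpy as np
import pytest
from hypothesis import given, strategies as st

from ldtscan import (
    GeneticMap,
    MaxLodSample,
    cd_adjusted_p,
    cd_threshold,
    conditional_threshold,
    empirical_exceedance,
    joint_exceedance,
    ldt_adjusted_p,
    ldt_adjusted_p_detail,
    ldt_threshold,
    location_distribution,
    quantile_threshold,
    sample_max_lod,
    simulate_population,
    validity_range,
)


def oracle_threshold(values, target):
    """Brute force over candidate order statistics: smallest sampled value
    whose strict exceedance is <= target."""
    values = np.asarray(values, dtype=float)
    feasible = [
        t for t in np.unique(values) if np.count_nonzero(values > t) <= target * values.size + 1e-9
    ]
    return min(feasible)


def _sample(deltas, lams, n_m):
    return MaxLodSample(np.asarray(deltas, float), np.asarray(lams), n_m=n_m)


class TestLocationDistribution:
    def test_uniform_counts_give_unit_alpha(self):
        s = _sample(np.arange(8), [1, 2, 3, 4, 1, 2, 3, 4], n_m=4)
        ld = location_distribution(s)
        assert np.allclose(ld.p_lambda, 0.25)
        assert np.allclose(ld.alpha, 1.0)
        assert validity_range(ld) == pytest.approx(1.0)

    def test_biased_counts_hand_evaluation(self):
        # counts (500, 250, 125, 125) of 1000: alpha_i = 1/(n_m p_i)
        lams = np.repeat([1, 2, 3, 4], [500, 250, 125, 125])
        ld = location_distribution(_sample(np.ones(1000), lams, n_m=4))
        assert np.allclose(ld.p_lambda, [0.5, 0.25, 0.125, 0.125])
        assert np.allclose(ld.alpha, [0.5, 1.0, 2.0, 2.0])
        assert validity_range(ld) == pytest.approx(0.5)

    def test_zero_count_marker_flagged_not_silent(self):
        ld = location_distribution(_sample([1.0, 2.0], [1, 1], n_m=2))
        assert ld.zero_count_markers == (2,)
        assert np.isnan(ld.alpha[1])
        assert validity_range(ld) == 0.0

    def test_laplace_smoothing_is_explicit(self):
        ld = location_distribution(_sample([1.0, 2.0], [1, 1], n_m=2), smoothing=True)
        assert ld.smoothed
        assert ld.zero_count_markers == ()
        assert ld.p_lambda[1] > 0


class TestExceedanceAndQuantile:
    def test_counting(self):
        v = np.arange(1, 101, dtype=float)
        assert empirical_exceedance(v, 80) == pytest.approx(0.20)
        assert empirical_exceedance(v, 0) == 1.0
        assert empirical_exceedance(v, 100) == 0.0

    def test_quantile_examples(self):
        v = np.arange(1, 101, dtype=float)
        assert quantile_threshold(v, 0.20) == 80.0
        assert quantile_threshold(v, 1.0) == 1.0
        assert quantile_threshold(v, 0.001) == 100.0  # below 1/n: the maximum

    @given(
        st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=50),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_quantile_matches_brute_force_with_ties(self, vals, target):
        v = np.asarray(vals, dtype=float)
        t = quantile_threshold(v, target)
        assert t == oracle_threshold(v, target)
        assert empirical_exceedance(v, t) <= target + 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    def test_exceedance_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(50)
        t = rng.standard_normal()
        assert empirical_exceedance(v, t) == np.sum(v > t) / 50


class TestCdThreshold:
    def test_counting_example(self):
        s = _sample(np.arange(1, 101), np.ones(100, dtype=int), n_m=1)
        res = cd_threshold(s, 0.20)
        assert np.all(res.T == 80.0)
        assert res.method == "CD"

    def test_extreme_gamma_returns_max(self):
        s = _sample(np.arange(1, 101), np.ones(100, dtype=int), n_m=1)
        assert np.all(cd_threshold(s, 0.005).T == 100.0)

    def test_independent_of_locations(self):
        deltas = np.arange(1, 101, dtype=float)
        a = cd_threshold(_sample(deltas, np.ones(100, dtype=int), n_m=2), 0.3)
        rng = np.random.default_rng(0)
        b = cd_threshold(_sample(deltas, rng.integers(1, 3, 100), n_m=2), 0.3)
        assert np.array_equal(a.T, b.T)


class TestConditionalThreshold:
    def test_two_stratum_toy(self):
        deltas = np.concatenate([np.arange(1, 11), np.arange(11, 21)]).astype(float)
        lams = np.repeat([1, 2], 10)
        res = conditional_threshold(_sample(deltas, lams, n_m=2), 0.2)
        assert res.T.tolist() == [8.0, 18.0]

    def test_single_point_stratum(self):
        res = conditional_threshold(_sample([5.0, 1.0], [1, 2], n_m=2), 0.5)
        assert res.T[0] == 5.0

    def test_zero_count_marker_is_descriptive_error(self):
        with pytest.raises(ValueError, match="marker 2.*5000"):
            conditional_threshold(_sample([1.0, 2.0], [1, 1], n_m=2), 0.2)


class TestLdtThreshold:
    def test_exchangeable_sample_equals_cd(self):
        # identical conditional distributions + uniform lambda -> LDT == CD
        deltas = np.tile(np.arange(1, 21, dtype=float), 4)
        lams = np.repeat([1, 2, 3, 4], 20)
        s = _sample(deltas, lams, n_m=4)
        assert np.array_equal(ldt_threshold(s, 0.2).T, cd_threshold(s, 0.2).T)

    def test_validity_error_at_and_above_bound(self, toy_sample_3m):
        v = validity_range(location_distribution(toy_sample_3m))
        assert v == pytest.approx(0.75)
        for gamma in (v, v + 0.1):
            with pytest.raises(ValueError, match="valid range"):
                ldt_threshold(toy_sample_3m, gamma)
        ldt_threshold(toy_sample_3m, v - 1e-9)  # just inside: succeeds

    def test_joint_exceedance_is_constant_share(self, toy_sample_3m):
        # brute-force check of the defining property on the build sample:
        # per-marker joint exceedance == gamma / n_m (up to quantile steps)
        gamma = 0.3
        res = ldt_threshold(toy_sample_3m, gamma)
        per, total = joint_exceedance(toy_sample_3m, res.T)
        budget = gamma / toy_sample_3m.n_m
        assert np.all(per <= budget + 1e-12)
        # distinct delta values: each marker achieves its full budget share
        assert np.allclose(per, budget)
        assert total == pytest.approx(gamma)

    def test_thresholds_are_minimal(self, toy_sample_3m):
        # lowering any marker's threshold to the next lower conditional
        # order statistic would overspend that marker's error budget
        gamma = 0.3
        res = ldt_threshold(toy_sample_3m, gamma)
        budget = gamma / toy_sample_3m.n_m
        for i in range(1, 4):
            cond = np.sort(toy_sample_3m.conditional_deltas(i))
            lower = cond[cond < res.T[i - 1]]
            if lower.size:
                trial = res.T.copy()
                trial[i - 1] = lower[-1]
                per, _ = joint_exceedance(toy_sample_3m, trial)
                assert per[i - 1] > budget + 1e-12

    def test_positive_bias_lowers_threshold(self):
        # marker 2 attains the max rarely (alpha > 1): its LDT threshold
        # must drop below its conditional-gamma threshold
        rng = np.random.default_rng(1)
        deltas = rng.random(200)
        lams = np.repeat([1, 2], [120, 80])
        s = _sample(deltas, lams, n_m=2)
        gamma = 0.2
        t_cond = conditional_threshold(s, gamma)
        t_ldt = ldt_threshold(s, gamma)
        assert t_ldt.T[1] < t_cond.T[1]
        assert t_ldt.T[0] > t_cond.T[0]  # over-represented marker rises

    def test_monotone_in_gamma(self, toy_sample_3m):
        prev = None
        for gamma in (0.05, 0.1, 0.2, 0.4, 0.6):
            T = ldt_threshold(toy_sample_3m, gamma).T
            if prev is not None:
                assert np.all(T <= prev + 1e-12)
            prev = T


class TestAdjustedP:
    def test_cd_counting(self):
        s = _sample(np.arange(1, 100), np.ones(99, dtype=int), n_m=1)
        assert cd_adjusted_p(s, 90) == pytest.approx(11 / 100)
        assert cd_adjusted_p(s, 1000) == pytest.approx(1 / 100)
        assert cd_adjusted_p(s, 0.5) == 1.0

    def test_ldt_extremes(self, toy_sample_3m):
        n_p = toy_sample_3m.n_p
        assert ldt_adjusted_p(toy_sample_3m, 1e9, 1) == pytest.approx(3 / (n_p + 1))
        assert ldt_adjusted_p(toy_sample_3m, -1.0, 1) == 1.0  # capped

    def test_ldt_matches_brute_force_joint_count(self, toy_sample_3m):
        obs = 107.0
        joint = np.sum((toy_sample_3m.lams == 2) & (toy_sample_3m.deltas >= obs))
        expected = 3 * (joint + 1) / (toy_sample_3m.n_p + 1)
        assert ldt_adjusted_p(toy_sample_3m, obs, 2) == pytest.approx(expected)

    def test_linearity_with_conditional_p(self, toy_sample_3m):
        # ldt p * alpha_i recovers the conditional permutation P-value
        # (up to the add-one bookkeeping of the two conventions)
        ld = location_distribution(toy_sample_3m)
        obs = 20.0
        _, p_unc, _ = ldt_adjusted_p_detail(toy_sample_3m, obs, 1)
        cond = toy_sample_3m.conditional_deltas(1)
        cond_p = (np.sum(cond >= obs) + 1) / (cond.size + 1)
        ratio = p_unc * ld.alpha[0] / cond_p
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_max_attainable_is_inverse_alpha(self, toy_sample_3m):
        ld = location_distribution(toy_sample_3m)
        for i in range(1, 4):
            _, _, p_max = ldt_adjusted_p_detail(toy_sample_3m, 0.0, i)
            assert p_max == pytest.approx(1 / ld.alpha[i - 1])

    def test_monotone_in_observed_lod(self, toy_sample_3m):
        grid = np.linspace(0, 250, 40)
        cd = [cd_adjusted_p(toy_sample_3m, t) for t in grid]
        ldt = [ldt_adjusted_p(toy_sample_3m, t, 2) for t in grid]
        assert np.all(np.diff(cd) <= 1e-15)
        assert np.all(np.diff(ldt) <= 1e-15)

    def test_invalid_marker(self, toy_sample_3m):
        with pytest.raises(ValueError):
            ldt_adjusted_p(toy_sample_3m, 1.0, 4)


class TestSimulationProperties:
    def test_in_sample_gwer_identity(self):
        """On the very sample used to build it, T_LDT spends at most the
        full error budget gamma and at least gamma - n_m/n_p of it."""
        m = GeneticMap.from_positions(["1"] * 8, [0, 1, 2, 3, 20, 40, 60, 80])
        pop = simulate_population(m, 120, seed=5)
        s = sample_max_lod(pop, 20_000, seed=6)
        gamma = 0.25
        res = ldt_threshold(s, gamma)
        per, total = joint_exceedance(s, res.T)
        assert np.all(per <= gamma / s.n_m + 1e-12)
        assert gamma - s.n_m / s.n_p - 1e-12 <= total <= gamma + 1e-12

    def test_local_rate_constant_for_ldt_not_cd(self):
        """Under location bias the CD threshold's per-marker error shares
        spread widely; the LDT shares stay pinned at gamma / n_m."""
        m = GeneticMap.from_positions(["1"] * 8, [0, 1, 2, 3, 20, 40, 60, 80])
        pop = simulate_population(m, 120, seed=7)
        s = sample_max_lod(pop, 20_000, seed=8)
        gamma = 0.25
        per_cd, _ = joint_exceedance(s, cd_threshold(s, gamma).T)
        per_ldt, _ = joint_exceedance(s, ldt_threshold(s, gamma).T)
        assert per_cd.max() - per_cd.min() > 5 * (per_ldt.max() - per_ldt.min() + 1e-12)
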