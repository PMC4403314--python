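"""van Rossum distance, coincidence factor, reliability and Poisson baselines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evospike.metrics import (coincidence_factor, expected_coincidence_poisson,
                              expected_van_rossum_poisson,
                              intrinsic_reliability, van_rossum_distance,
                              van_rossum_to_function)
from evospike.spike_trains import (SampledTrace, SpikeTrain, TrialSet,
                                   average_function, filter_train)
from evospike.synthetic import generate_poisson_train


def random_train(rng, n_max=40, T=1000.0):
    n = int(rng.integers(0, n_max))
    return SpikeTrain(np.sort(rng.uniform(0, T, n)), T)


class TestVanRossum:
    def test_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            u = random_train(rng)
            assert van_rossum_distance(u, u, 12.0) == pytest.approx(0.0, abs=1e-7)

    def test_single_spike_vs_empty_is_unity(self):
        e = SpikeTrain([], 100.0)
        for t0 in (0.0, 17.3, 99.0):
            for tau in (1.0, 10.0, 250.0):
                d = van_rossum_distance(SpikeTrain([t0], 100.0), e, tau)
                assert d == pytest.approx(1.0, rel=1e-12)

    def test_two_single_spikes_closed_form(self):
        d = van_rossum_distance(SpikeTrain([0.0], 100.0),
                                SpikeTrain([5.0], 100.0), 10.0)
        assert d == pytest.approx(math.sqrt(2.0 - 2.0 * math.exp(-0.5)), rel=1e-12)

    def test_efficient_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            u = random_train(rng, 200, 2000.0)
            v = random_train(rng, 200, 2000.0)
            tau = float(rng.uniform(1.0, 100.0))
            de = van_rossum_distance(u, v, tau, "efficient")
            db = van_rossum_distance(u, v, tau, "brute")
            assert de == pytest.approx(db, rel=1e-10, abs=1e-10)

    def test_matches_numerical_integration(self):
        rng = np.random.default_rng(3)
        tau = 15.0
        for _ in range(5):
            u, v = random_train(rng, 20), random_train(rng, 20)
            fu, fv = filter_train(u, tau), filter_train(v, tau)
            t = np.linspace(0, 1000.0 + 20 * tau, 400001)
            diff = fu(t) - fv(t)
            d_num = math.sqrt(np.trapezoid(diff ** 2, t))
            d = van_rossum_distance(u, v, tau)
            assert d == pytest.approx(d_num, rel=1e-4, abs=1e-6)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(4)
        tau = 10.0
        for _ in range(200):
            a, b, c = (random_train(rng, 15, 300.0) for _ in range(3))
            dab = van_rossum_distance(a, b, tau)
            dba = van_rossum_distance(b, a, tau)
            dac = van_rossum_distance(a, c, tau)
            dcb = van_rossum_distance(c, b, tau)
            assert dab >= 0
            assert dab == pytest.approx(dba, rel=1e-10, abs=1e-12)
            assert dab <= dac + dcb + 1e-9

    def test_monotone_in_tau_for_single_spike_pair(self):
        u, v = SpikeTrain([100.0], 400.0), SpikeTrain([130.0], 400.0)
        taus = np.linspace(2.0, 200.0, 40)
        d = [van_rossum_distance(u, v, t) for t in taus]
        assert np.all(np.diff(d) <= 1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        u, v = random_train(rng, 25), random_train(rng, 25)
        tau = float(rng.uniform(0.5, 300.0))
        assert van_rossum_distance(u, v, tau) == pytest.approx(
            van_rossum_distance(v, u, tau), rel=1e-10, abs=1e-12)

    def test_tau_validation(self):
        u = SpikeTrain([1.0], 10.0)
        with pytest.raises(ValueError):
            van_rossum_distance(u, u, -1.0)


class TestVanRossumToFunction:
    def test_distance_to_own_function_is_zero(self):
        u = SpikeTrain([5.0, 30.0, 77.0], 100.0)
        g = filter_train(u, 10.0)
        assert van_rossum_to_function(u, g) == pytest.approx(0.0, abs=1e-8)
        g2 = average_function(TrialSet([u, u]), 10.0)
        assert van_rossum_to_function(u, g2) == pytest.approx(0.0, abs=1e-8)

    def test_distance_to_two_train_average(self):
        # with g = (f_a + f_b)/2: d(a, g) = d(a, b)/2
        rng = np.random.default_rng(5)
        a, b = random_train(rng, 20), random_train(rng, 20)
        tau = 8.0
        g = average_function(TrialSet([a, b]), tau)
        expect = van_rossum_distance(a, b, tau) / 2.0
        assert van_rossum_to_function(a, g) == pytest.approx(expect, rel=1e-10)


class TestCoincidenceFactor:
    def test_identical_trains_give_unity(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            u = random_train(rng, 50, 2000.0)
            if u.n_spikes == 0:
                continue
            res = coincidence_factor(u, u, 2.0)
            assert res.gamma == pytest.approx(1.0, rel=1e-12)
            assert res.n_coinc == u.n_spikes

    def test_empty_model_closed_form(self):
        rng = np.random.default_rng(7)
        target = random_train(rng, 30, 1000.0)
        delta = 2.0
        f = target.n_spikes / target.duration
        res = coincidence_factor(SpikeTrain([], 1000.0), target, delta)
        assert res.gamma == pytest.approx(-4 * delta * f / (1 - 2 * delta * f),
                                          rel=1e-12)

    def test_poisson_model_is_chance_level(self):
        rng = np.random.default_rng(8)
        T, lam, delta = 2000.0, 0.01, 2.0
        target = SpikeTrain(np.sort(rng.uniform(0, T, 20)), T)
        gammas = []
        for _ in range(200):
            n = rng.poisson(lam * T)
            model = SpikeTrain(np.sort(rng.uniform(0, T, n)), T)
            gammas.append(coincidence_factor(model, target, delta).gamma)
        se = np.std(gammas, ddof=1) / math.sqrt(len(gammas))
        assert abs(np.mean(gammas)) < 3 * se + 0.02

    def test_one_to_one_matching_prevents_double_counting(self):
        # one model spike near two target spikes counts once
        target = SpikeTrain([10.0, 11.0], 100.0)
        model = SpikeTrain([10.5], 100.0)
        assert coincidence_factor(model, target, 2.0).n_coinc == 1

    def test_window_requirement(self):
        dense = SpikeTrain(np.arange(1.0, 99.0, 2.0), 100.0)
        with pytest.raises(ValueError):
            coincidence_factor(dense, dense, 2.0)  # 2*f*delta = 2

    def test_two_empty_trains_degenerate_match(self):
        e = SpikeTrain([], 100.0)
        assert coincidence_factor(e, e, 2.0).gamma == 1.0


class TestIntrinsicReliability:
    def test_identical_copies(self):
        u = SpikeTrain([10.0, 50.0, 90.0], 200.0)
        res = intrinsic_reliability(TrialSet([u, u, u]), 2.0)
        assert res.gamma_i == pytest.approx(1.0)
        assert res.cluster_size == pytest.approx(0.0, abs=1e-7)

    def test_two_trials_mean_of_directed_values(self):
        rng = np.random.default_rng(9)
        a, b = random_train(rng, 25), random_train(rng, 25)
        res = intrinsic_reliability(TrialSet([a, b]), 2.0)
        g1 = coincidence_factor(a, b, 2.0).gamma
        g2 = coincidence_factor(b, a, 2.0).gamma
        assert res.gamma_i == pytest.approx(0.5 * (g1 + g2))

    def test_jittered_beats_independent_poisson(self):
        rng = np.random.default_rng(10)
        T = 2000.0
        base = np.sort(rng.uniform(0, T - 10, 25))
        jittered = TrialSet([
            SpikeTrain(np.sort(np.clip(base + rng.normal(0, 1.0, base.size),
                                       0, T)), T)
            for _ in range(5)])
        poisson = TrialSet([
            SpikeTrain(np.sort(rng.uniform(0, T, 25)), T) for _ in range(5)])
        gi_j = intrinsic_reliability(jittered, 2.0).gamma_i
        gi_p = intrinsic_reliability(poisson, 2.0).gamma_i
        assert gi_j > gi_p

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            intrinsic_reliability(TrialSet([SpikeTrain([1.0], 10.0)]), 2.0)


class TestPoissonExpectations:
    def test_zero_rate_reduces_to_empty_train_case(self):
        rate = SampledTrace(np.zeros(1000), dt=1.0)
        target = SpikeTrain([100.0, 300.0, 700.0], 1000.0)
        delta = 2.0
        f = 3 / 1000.0
        val = expected_coincidence_poisson(rate, target, delta, n_mc=10, seed=0)
        assert val == pytest.approx(-4 * delta * f / (1 - 2 * delta * f),
                                    rel=1e-9)

    def test_narrow_bumps_at_target_spikes_approach_ceiling(self):
        # Narrow rate bumps centred on the target spikes: every Poisson spike
        # is coincident, but Poisson count dispersion caps the expected
        # factor at max_m 2(1-e^-m)/(1+m) ~= 0.648 (m = spikes per bump),
        # reached near m ~= 1.25.  Check we approach that ceiling.
        T = 1000.0
        target = SpikeTrain([100.0, 300.0, 700.0], T)
        t = np.arange(0, T, 0.5)
        rate = np.zeros_like(t)
        for s in target.times:
            rate[np.abs(t - s) <= 0.5] = 1.25  # m ~= 1.25 spikes per bump
        val = expected_coincidence_poisson(SampledTrace(rate, dt=0.5), target,
                                          2.0, n_mc=400, seed=1)
        assert 0.5 < val <= 0.75

    def test_monte_carlo_stability_under_doubling(self):
        rng = np.random.default_rng(11)
        T = 2000.0
        target = SpikeTrain(np.sort(rng.uniform(0, T, 20)), T)
        t = np.arange(0, T, 1.0)
        rate = SampledTrace(0.01 * (1 + 0.5 * np.sin(t / 50.0)), dt=1.0)
        draws = [expected_coincidence_poisson(rate, target, 2.0, n_mc=100,
                                              seed=s) for s in range(12)]
        se = np.std(draws, ddof=1)
        v1 = expected_coincidence_poisson(rate, target, 2.0, n_mc=100, seed=100)
        v2 = expected_coincidence_poisson(rate, target, 2.0, n_mc=200, seed=101)
        assert abs(v1 - v2) < 3 * se + 1e-9

    def test_expected_van_rossum_zero_rate_is_norm(self):
        rng = np.random.default_rng(12)
        u = random_train(rng, 15, 500.0)
        tau = 10.0
        rate = SampledTrace(np.zeros(5001), dt=0.1)
        val = expected_van_rossum_poisson(rate, u, tau)
        expect = van_rossum_distance(u, SpikeTrain([], 500.0), tau)
        assert val == pytest.approx(expect, rel=1e-3)

    def test_empty_everything_is_zero(self):
        rate = SampledTrace(np.zeros(100), dt=1.0)
        val = expected_van_rossum_poisson(rate, SpikeTrain([], 100.0), 10.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_lower_bounds_monte_carlo_mean_distance(self):
        # distance between expected functions <= mean distance (Jensen +
        # Poisson variance), checked against 1000 thinning draws
        rng = np.random.default_rng(13)
        T = 1000.0
        u = SpikeTrain(np.sort(rng.uniform(0, T, 12)), T)
        t = np.arange(0, T, 1.0)
        rate = SampledTrace(0.012 * (1 + 0.8 * np.sin(t / 100.0)), dt=1.0)
        tau = 10.0
        val = expected_van_rossum_poisson(rate, u, tau)
        draws = [van_rossum_distance(generate_poisson_train(rate, s), u, tau)
                 for s in range(1000)]
        assert val <= np.mean(draws)

    def test_negative_rate_rejected(self):
        rate = SampledTrace(np.array([0.1, -0.1, 0.1]), dt=1.0)
        with pytest.raises(ValueError):
            expected_van_rossum_poisson(rate, SpikeTrain([], 3.0), 5.0)
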