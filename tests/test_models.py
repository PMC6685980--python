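"""Toxicokinetics, survival functions and the conditional-binomial likelihood."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import gutspy as g
from gutspy import models as m


def _random_pulse_profile(rng):
    n = rng.integers(1, 4)
    width = rng.uniform(0.5, 2.0)
    starts, t = [], 0.0
    for _ in range(n):
        t += rng.uniform(0.0, 4.0)
        starts.append(t)
        t += width
    return g.make_pulse_profile(n, rng.uniform(1.0, 10.0), width, starts, t + rng.uniform(1, 5))


def _ode_damage(profile, k_d, t_end):
    """Independent stiff-solver oracle for the damage ODE."""
    sol = solve_ivp(
        lambda t, y: k_d * (profile.concentration_at(float(t)) - y[0]),
        (0.0, t_end), [0.0], rtol=1e-10, atol=1e-12, max_step=0.05, dense_output=True,
    )
    return sol


class TestScaledDamage:
    def test_constant_exposure_closed_form(self):
        d = g.scaled_damage(g.constant_profile(2.0), math.log(2), [1.0])
        assert d[0] == pytest.approx(1.0)

    def test_initial_condition_zero(self, two_pulse_profile):
        assert g.scaled_damage(two_pulse_profile, 1.3, [0.0])[0] == 0.0

    def test_converges_to_concentration(self):
        d = g.scaled_damage(g.constant_profile(3.0), 0.5, [200.0])
        assert d[0] == pytest.approx(3.0, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_ode_oracle_on_pulse_profiles(self, seed):
        rng = np.random.default_rng(seed)
        profile = _random_pulse_profile(rng)
        k_d = rng.uniform(0.1, 2.0)
        t_end = profile.times[-1]
        grid = np.linspace(0.01, t_end, 13)
        ours = g.scaled_damage(profile, k_d, grid)
        oracle = _ode_damage(profile, k_d, t_end)
        ref = oracle.sol(grid)[0]
        assert np.allclose(ours, ref, rtol=1e-6, atol=1e-9)

    def test_linear_in_the_forcing(self, two_pulse_profile):
        grid = np.linspace(0, 12, 31)
        scale = 3.7
        direct = g.scaled_damage(two_pulse_profile.scaled(scale), 0.9, grid)
        scaled = scale * g.scaled_damage(two_pulse_profile, 0.9, grid)
        assert np.allclose(direct, scaled, rtol=1e-14, atol=1e-13)

    def test_bounded_by_running_peak_concentration(self, two_pulse_profile):
        grid = np.linspace(0, 12, 100)
        d = g.scaled_damage(two_pulse_profile, 1.1, grid)
        assert np.all(d >= -1e-15)
        assert np.all(d <= two_pulse_profile.concentrations.max() + 1e-12)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            g.scaled_damage(g.constant_profile(1.0), 0.0, [1.0])


class TestMaxDamage:
    def test_constant_exposure_is_endpoint_value(self):
        assert g.max_damage(g.constant_profile(2.0), math.log(2), 1.0) == pytest.approx(1.0)

    def test_single_pulse_peak_at_pulse_end(self):
        p = g.make_pulse_profile(1, 5.0, 1.0, [0.0], 10.0)
        at_end = g.scaled_damage(p, 1.0, [1.0])[0]
        assert g.max_damage(p, 1.0, 8.0) == pytest.approx(at_end, rel=1e-12)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_dense_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        profile = _random_pulse_profile(rng)
        k_d = rng.uniform(0.2, 2.0)
        t = profile.times[-1] * 0.9
        # dense grid plus the profile knots, where the damage peak can sit
        knots = profile.times[(profile.times > 0) & (profile.times <= t)]
        grid = np.union1d(np.linspace(1e-6, t, 200001), knots)
        dense = g.scaled_damage(profile, k_d, grid)
        assert g.max_damage(profile, k_d, t) == pytest.approx(dense.max(), rel=1e-6)


class TestDepurationTime:
    def test_half_life(self):
        assert g.depuration_time(math.log(2), 50) == pytest.approx(1.0)

    def test_small_x_limit(self):
        assert g.depuration_time(1.0, 1e-9) == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_decay_root(self):
        # time at which exp(-k_d t) = 0.5 for k_d = 0.1
        assert g.depuration_time(0.1, 50) == pytest.approx(math.log(2) / 0.1)

    @pytest.mark.parametrize("x", [0, 100, -5, 120])
    def test_domain_errors(self, x):
        with pytest.raises(ValueError):
            g.depuration_time(1.0, x)


class TestSurvivalSD:
    def test_below_threshold_only_background(self):
        p = g.SDParams(k_d=1.0, b_w=5.0, z=3.0, h_b=0.1)
        t = np.array([0.0, 1.0, 4.0])
        S = g.survival_sd(p, g.constant_profile(2.0), t)  # C < z: never exceeded
        assert np.allclose(S, np.exp(-0.1 * t), rtol=1e-12)

    def test_no_exposure_no_background_is_one(self):
        p = g.SDParams(k_d=1.0, b_w=1.0, z=0.5, h_b=0.0)
        S = g.survival_sd(p, g.constant_profile(0.0), [0.0, 5.0, 50.0])
        assert np.all(S == 1.0)

    def test_constant_exposure_matches_quadrature_oracle(self):
        p = g.SDParams(k_d=0.7, b_w=0.5, z=1.0, h_b=0.02)
        C, t = 3.0, 4.0
        ours = g.survival_sd(p, g.constant_profile(C), [t])[0]
        dmg = lambda tau: C * (1 - math.exp(-p.k_d * tau))
        H = quad(lambda tau: max(dmg(tau) - p.z, 0.0), 0, t, limit=200)[0]
        assert ours == pytest.approx(math.exp(-p.h_b * t - p.b_w * H), rel=1e-8)

    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_pulsed_exposure_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        profile = _random_pulse_profile(rng)
        p = g.SDParams(k_d=rng.uniform(0.2, 1.5), b_w=rng.uniform(0.1, 1.0),
                       z=rng.uniform(0.2, 3.0), h_b=rng.uniform(0, 0.05))
        t = profile.times[-1] * 0.8
        oracle = _ode_damage(profile, p.k_d, t)
        H = quad(lambda tau: max(oracle.sol(tau)[0] - p.z, 0.0), 0, t, limit=400)[0]
        ours = g.survival_sd(p, profile, [t])[0]
        assert ours == pytest.approx(math.exp(-p.h_b * t - p.b_w * H), rel=1e-7)

    def test_non_increasing_and_dominated_by_weaker_exposure(self, two_pulse_profile):
        p = g.SDParams(k_d=0.8, b_w=0.5, z=1.0, h_b=0.01)
        grid = np.linspace(0, 12, 60)
        S = g.survival_sd(p, two_pulse_profile, grid)
        assert np.all(np.diff(S) <= 1e-14)
        S_weaker = g.survival_sd(p, two_pulse_profile.scaled(0.5), grid)
        assert np.all(S_weaker >= S - 1e-14)


class TestSurvivalIT:
    def test_median_threshold_gives_half_survival(self):
        p = g.ITParams(k_d=50.0, m_w=2.0, beta=2.0, h_b=0.0)  # fast TK: D ~ C_w
        S = g.survival_it(p, g.constant_profile(2.0), [5.0])
        assert S[0] == pytest.approx(0.5, rel=1e-6)

    def test_no_exposure_background_only(self):
        p = g.ITParams(k_d=1.0, m_w=1.0, beta=2.0, h_b=0.07)
        t = np.array([0.0, 2.0, 9.0])
        assert np.allclose(g.survival_it(p, g.constant_profile(0.0), t), np.exp(-0.07 * t))

    def test_unit_shape_at_double_median(self):
        # beta=1, C=2 m_w, k_d=ln2, t=1: max damage = m_w so S = 0.5
        p = g.ITParams(k_d=math.log(2), m_w=1.0, beta=1.0, h_b=0.0)
        S = g.survival_it(p, g.constant_profile(2.0), [1.0])
        assert S[0] == pytest.approx(0.5, rel=1e-12)

    def test_non_increasing_under_pulses(self, two_pulse_profile):
        p = g.ITParams(k_d=0.6, m_w=1.5, beta=2.5, h_b=0.01)
        S = g.survival_it(p, two_pulse_profile, np.linspace(0, 12, 80))
        assert np.all(np.diff(S) <= 1e-14)


class TestVectorisedConstantPaths:
    """The sampler's closed-form constant-exposure survival must agree
    exactly with the generic piecewise-analytic path."""

    @pytest.mark.parametrize("seed", range(5))
    def test_sd(self, seed):
        rng = np.random.default_rng(seed)
        p = g.SDParams(*rng.uniform([0.1, 0.05, 0.0, 0.0], [2.0, 2.0, 4.0, 0.1]))
        C = rng.uniform(0, 8)
        t = np.linspace(0, 6, 13)
        a = g.survival_sd(p, g.constant_profile(C), t)
        b = m.sd_survival_constant(p.k_d, p.b_w, p.z, p.h_b, C, t)
        assert np.allclose(a, b, rtol=1e-12, atol=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_it(self, seed):
        rng = np.random.default_rng(seed)
        p = g.ITParams(*rng.uniform([0.1, 0.1, 0.3, 0.0], [2.0, 4.0, 5.0, 0.1]))
        C = rng.uniform(0, 8)
        t = np.linspace(0, 6, 13)
        a = g.survival_it(p, g.constant_profile(C), t)
        b = m.it_survival_constant(p.k_d, p.m_w, p.beta, p.h_b, C, t)
        assert np.allclose(a, b, rtol=1e-12, atol=0)


class TestLogLikelihood:
    def test_certain_data_has_zero_loglik(self):
        p = g.SDParams(k_d=1.0, b_w=1.0, z=1.0, h_b=0.0)
        ts = g.SurvivalTimeSeries(g.constant_profile(0.0, "c"),
                                  np.array([0.0, 2.0, 4.0]), np.array([20, 20, 20]))
        assert g.log_likelihood(p, g.SurvivalDataset([ts])) == 0.0

    def test_single_interval_binomial_mass(self):
        # S-ratio 0.5 from pure background mortality over 4 days
        p = g.SDParams(k_d=1.0, b_w=1.0, z=1.0, h_b=math.log(2) / 4)
        ts = g.SurvivalTimeSeries(g.constant_profile(0.0, "c"),
                                  np.array([0.0, 4.0]), np.array([20, 10]))
        expected = math.lgamma(21) - 2 * math.lgamma(11) + 20 * math.log(0.5)
        assert g.log_likelihood(p, g.SurvivalDataset([ts])) == pytest.approx(expected)

    def test_additive_over_series(self, sd_true, constant_sd_dataset):
        total = g.log_likelihood(sd_true, constant_sd_dataset)
        parts = sum(
            g.log_likelihood(sd_true, g.SurvivalDataset([s]))
            for s in constant_sd_dataset.series
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_impossible_data_is_minus_inf(self):
        # deaths observed although survival ratio is exactly 1
        p = g.SDParams(k_d=1.0, b_w=1.0, z=5.0, h_b=0.0)
        ts = g.SurvivalTimeSeries(g.constant_profile(1.0, "c"),
                                  np.array([0.0, 4.0]), np.array([20, 15]))
        assert g.log_likelihood(p, g.SurvivalDataset([ts])) == -np.inf

    def test_increasing_counts_rejected_at_construction(self):
        with pytest.raises(ValueError):
            g.SurvivalTimeSeries(g.constant_profile(0.0, "c"),
                                 np.array([0.0, 1.0]), np.array([10, 12]))
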