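"""LC(x,t), incipient LC and MF(x,t): closed forms, root-solves, monotonicity."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

import gutspy as g
from tests.conftest import degenerate_posterior, posterior_from_draws


def _invert_lc_it(params, x, t, hi=1e6):
    """Independent numerical inversion of the defining survival relation."""
    S0 = g.survival_it(params, g.constant_profile(0.0), [t])[0]
    target = S0 * (1 - x / 100.0)

    def f(C):
        return g.survival_it(params, g.constant_profile(C), [t])[0] - target

    return bisect(f, 1e-12, hi, xtol=1e-13, rtol=1e-12)


def _invert_mf(params, profile, x, t, survival_fn):
    """Root-solve S(MF * profile, t) = S(profile, t) (1 - x/100) by bisection."""
    S_base = survival_fn(params, profile, [t])[0]
    target = S_base * (1 - x / 100.0)

    def f(mf):
        return survival_fn(params, profile.scaled(mf), [t])[0] - target

    return bisect(f, 1e-9, 1e6, xtol=1e-13, rtol=1e-12)


class TestLcIt:
    def test_textbook_point(self):
        p = g.ITParams(k_d=math.log(2), m_w=2.0, beta=1.0, h_b=0.0)
        assert g.lc_it(p, 50, 1.0) == pytest.approx(4.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_matches_numerical_inversion(self, seed):
        rng = np.random.default_rng(seed)
        p = g.ITParams(k_d=rng.uniform(0.2, 2), m_w=rng.uniform(0.5, 4),
                       beta=rng.uniform(0.5, 4), h_b=rng.uniform(0, 0.05))
        x, t = rng.uniform(5, 95), rng.uniform(0.5, 8)
        assert g.lc_it(p, x, t) == pytest.approx(_invert_lc_it(p, x, t), rel=1e-6)

    def test_monotone_in_x(self, it_true):
        xs = [5, 20, 50, 80, 95]
        vals = [g.lc_it(it_true, x, 2.0) for x in xs]
        assert np.all(np.diff(vals) > 0)

    def test_extreme_x_rejected(self, it_true):
        with pytest.raises(ValueError):
            g.lc_it(it_true, 0, 1.0)
        with pytest.raises(ValueError):
            g.lc_it(it_true, 100, 1.0)


class TestLcSd:
    @pytest.mark.parametrize("seed", range(5))
    def test_defining_relation_residual(self, seed):
        rng = np.random.default_rng(seed)
        p = g.SDParams(k_d=rng.uniform(0.3, 2), b_w=rng.uniform(0.1, 2),
                       z=rng.uniform(0.3, 3), h_b=rng.uniform(0, 0.05))
        x, t = rng.uniform(5, 95), rng.uniform(1.0, 8)
        C = g.lc_sd(p, x, t)
        S = g.survival_sd(p, g.constant_profile(C), [t])[0]
        S0 = g.survival_sd(p, g.constant_profile(0.0), [t])[0]
        assert abs(S - S0 * (1 - x / 100.0)) < 1e-8

    def test_strictly_decreasing_in_time(self, sd_true):
        ts = [1.0, 2.0, 4.0, 8.0, 16.0]
        vals = [g.lc_sd(sd_true, 50, t) for t in ts]
        assert np.all(np.diff(vals) < 0)

    def test_converges_to_threshold(self, sd_true):
        # LC - z decays like -ln(1-x/100)/(b_w t), so the horizon must be
        # hundreds of days for 0.1% agreement
        assert g.lc_sd(sd_true, 30, 4000.0) == pytest.approx(sd_true.z, rel=1e-3)


class TestIncipient:
    def test_sd_incipient_is_z_for_any_x(self, sd_true):
        for x in (10, 50, 90):
            assert g.lc_incipient(sd_true, x) == sd_true.z

    def test_it_incipient_median(self, it_true):
        assert g.lc_incipient(it_true, 50) == pytest.approx(it_true.m_w)

    def test_it_incipient_unit_shape(self):
        p = g.ITParams(k_d=1.0, m_w=1.0, beta=1.0, h_b=0.0)
        assert g.lc_incipient(p, 75) == pytest.approx(3.0)
        # brute force: lc_it at very large t
        assert g.lc_it(p, 75, 5000.0) == pytest.approx(3.0, rel=1e-9)


class TestMfIt:
    def test_median_damage_point(self):
        # max damage = m_w, beta = 1, x = 50 -> MF = (100+50)/50 = 3
        p = g.ITParams(k_d=math.log(2), m_w=1.0, beta=1.0, h_b=0.0)
        prof = g.constant_profile(2.0)  # max damage at t=1 is m_w
        assert g.mf_it(p, prof, 50, 1.0) == pytest.approx(3.0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_matches_root_solve(self, seed, two_pulse_profile):
        rng = np.random.default_rng(seed)
        p = g.ITParams(k_d=rng.uniform(0.3, 1.5), m_w=rng.uniform(0.5, 3),
                       beta=rng.uniform(0.5, 4), h_b=rng.uniform(0, 0.05))
        x, t = rng.uniform(5, 95), rng.uniform(3, 11)
        ours = g.mf_it(p, two_pulse_profile, x, t)
        ref = _invert_mf(p, two_pulse_profile, x, t, g.survival_it)
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_control_baseline_variant(self, two_pulse_profile):
        p = g.ITParams(k_d=0.8, m_w=2.0, beta=2.0, h_b=0.03)
        x, t = 30.0, 8.0
        mf_c = g.mf_it(p, two_pulse_profile, x, t, baseline="control")
        S = g.survival_it(p, two_pulse_profile.scaled(mf_c), [t])[0]
        S0 = g.survival_it(p, g.constant_profile(0.0), [t])[0]
        assert S == pytest.approx(S0 * (1 - x / 100.0), rel=1e-9)

    def test_monotone_in_x_and_t(self, it_true, two_pulse_profile):
        xs = [5, 20, 50, 80]
        vals = [g.mf_it(it_true, two_pulse_profile, x, 10.0) for x in xs]
        assert np.all(np.diff(vals) > 0)
        ts = [2.0, 5.0, 8.0, 12.0]
        vals_t = [g.mf_it(it_true, two_pulse_profile, 50, t) for t in ts]
        assert np.all(np.diff(vals_t) <= 1e-12)

    def test_zero_profile_rejected(self, it_true):
        with pytest.raises(ValueError):
            g.mf_it(it_true, g.constant_profile(0.0), 50, 4.0)


class TestMfSd:
    @pytest.mark.parametrize("seed", range(5))
    def test_defining_equation_residual(self, seed, two_pulse_profile):
        rng = np.random.default_rng(seed)
        p = g.SDParams(k_d=rng.uniform(0.3, 1.5), b_w=rng.uniform(0.1, 1.5),
                       z=rng.uniform(0.2, 2.5), h_b=rng.uniform(0, 0.05))
        x, t = rng.uniform(5, 95), rng.uniform(3, 11)
        mf = g.mf_sd(p, two_pulse_profile, x, t)
        S_mf = g.survival_sd(p, two_pulse_profile.scaled(mf), [t])[0]
        S_base = g.survival_sd(p, two_pulse_profile, [t])[0]
        assert abs(S_mf - S_base * (1 - x / 100.0)) < 1e-8

    def test_matches_direct_root_solve(self, sd_true, two_pulse_profile):
        x, t = 40.0, 9.0
        ours = g.mf_sd(sd_true, two_pulse_profile, x, t)
        ref = _invert_mf(sd_true, two_pulse_profile, x, t, g.survival_sd)
        assert ours == pytest.approx(ref, rel=1e-8)

    def test_small_x_approaches_identity_scaling(self, sd_true, two_pulse_profile):
        assert g.mf_sd(sd_true, two_pulse_profile, 0.1, 10.0) == pytest.approx(1.0, rel=0.05)

    def test_constant_profile_decreasing_toward_asymptote(self, sd_true):
        prof = g.constant_profile(1.0)
        ts = [1.0, 2.0, 4.0, 8.0, 20.0, 60.0]
        vals = [g.mf_sd(sd_true, prof, 50, t) for t in ts]
        assert np.all(np.diff(vals) < 0)
        # asymptote: MF * C must still exceed z, so MF >= z / C
        assert vals[-1] > sd_true.z / 1.0


class TestEndpointDistribution:
    def test_degenerate_posterior_collapses(self, sd_true):
        post = degenerate_posterior(sd_true)
        df = g.endpoint_distribution(post, lambda p, t: g.lc_sd(p, 50, t), [2.0, 4.0])
        assert (df["median"] == df["q025"]).all()
        assert (df["median"] == df["q975"]).all()

    def test_quantiles_match_direct_sort(self, sd_results):
        post = sd_results.posterior
        df = g.endpoint_distribution(post, lambda p, t: g.lc_sd(p, 50, t), [4.0])
        vals = np.array([g.lc_sd(p, 50, 4.0) for p in post.param_objects()])
        q = np.quantile(vals, [0.025, 0.5, 0.975])
        assert df.loc[0, ["q025", "median", "q975"]].to_numpy() == pytest.approx(q)

    def test_undefined_draws_are_dropped_and_counted(self, sd_true):
        post = degenerate_posterior(sd_true, n_draws=10)

        calls = {"n": 0}

        def flaky(p, t):
            calls["n"] += 1
            if calls["n"] % 4 == 0:
                raise ValueError("undefined for this draw")
            return g.lc_sd(p, 50, t)

        df = g.endpoint_distribution(post, flaky, [4.0])
        assert df.loc[0, "n_dropped"] == 2

    def test_mostly_undefined_raises(self, sd_true):
        post = degenerate_posterior(sd_true, n_draws=10)

        def broken(p, t):
            raise ValueError("no value")

        with pytest.raises(RuntimeError):
            g.endpoint_distribution(post, broken, [4.0])

    def test_lc_uncertainty_wider_at_extreme_x(self, sd_results):
        post = sd_results.posterior
        widths = {}
        for x in (10.0, 50.0):
            df = g.endpoint_distribution(post, lambda p, _t, _x=x: g.lc_sd(p, _x, _t), [4.0])
            med = df.loc[0, "median"]
            widths[x] = (df.loc[0, "q975"] - df.loc[0, "q025"]) / med
        assert widths[10.0] > widths[50.0]
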