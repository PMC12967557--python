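"""Mixing-proportion and endpoint estimators, limit simulation, CIs."""

import math

import numpy as np
import pytest

from semimix import (EmpiricalCDF, alpha_confidence_interval, background,
                     default_bn, estimate_a0, estimate_alpha,
                     sample_setting, simulate_alpha_limit, setting_truth)
from semimix.empirical import DomainError
from semimix.estimate import LimitSample


class TestAlpha:
    def test_worked_example_left(self, uniform_bg):
        est = estimate_alpha([0.1, 0.2, 0.3, 0.9], uniform_bg, 0.8, "left_support")
        assert est.alpha_hat == pytest.approx(9 / 14)

    def test_single_point_right(self, uniform_bg):
        est = estimate_alpha([0.4], uniform_bg, 0.5, "right_support")
        assert est.alpha_hat == 0.0

    def test_bounded_and_monotone_in_search_region(self, uniform_bg, rng):
        # enlarging the search region (larger kappa0 here) never decreases alpha
        s = rng.random(200)
        prev = -1.0
        for k0 in (0.5, 0.6, 0.7, 0.8, 0.9):
            a = estimate_alpha(s, uniform_bg, k0, "left_support").alpha_hat
            assert 0.0 <= a <= 1.0
            assert a >= prev - 1e-12
            prev = a

    def test_mirror_equivariance(self, uniform_bg, rng):
        s = np.sort(rng.random(100) * 0.9)
        a_left = estimate_alpha(s, uniform_bg, 0.8, "left_support")
        a_right = estimate_alpha(1 - s, uniform_bg, 0.2, "right_support")
        assert a_left.alpha_hat == pytest.approx(a_right.alpha_hat, abs=1e-12)
        e_left = estimate_a0(s, uniform_bg, 0.8, a_left)
        e_right = estimate_a0(1 - s, uniform_bg, 0.2, a_right)
        assert e_left.a_hat == pytest.approx(1 - e_right.a_hat, abs=1e-12)


class TestEndpoint:
    def test_worked_example(self, uniform_bg):
        s = [0.1, 0.2, 0.3, 0.9]
        a = estimate_alpha(s, uniform_bg, 0.8, "left_support")
        est = estimate_a0(s, uniform_bg, 0.8, a, b_n=math.log(math.log(4)))
        assert est.a_hat == pytest.approx(0.3)
        assert est.attained

    def test_empty_set_flag(self, uniform_bg):
        # no data below kappa0 satisfies the criterion -> flagged, a_hat = kappa0
        s = [0.95, 0.99]
        a = estimate_alpha(s, uniform_bg, 0.9, "left_support")
        est = estimate_a0(s, uniform_bg, 0.9, a, b_n=0.01)
        assert not est.attained and est.a_hat == 0.9

    def test_unbounded_threshold_rejected(self, uniform_bg):
        s = [0.1, 0.5]
        a = estimate_alpha(s, uniform_bg, 0.9, "left_support")
        with pytest.raises(DomainError):
            estimate_a0(s, uniform_bg, 0.9, a, b_n=100.0)

    def test_default_bn_guard(self):
        assert default_bn(1000) == pytest.approx(math.log(math.log(1000)))
        assert default_bn(2) == 0.1   # log log 2 < 0 -> positive fallback

    def test_rate_constant_setting_1a(self, uniform_bg):
        """Median of (sqrt(n)/b_n)(a0 - a_hat) near 1/f_s(a0) = 0.6."""
        rng = np.random.default_rng(99)
        n = 10_000
        vals = []
        for _ in range(200):
            s = sample_setting("1a", n, rng)
            a = estimate_alpha(s, uniform_bg, 0.8, "left_support")
            est = estimate_a0(s, uniform_bg, 0.8, a)
            vals.append(math.sqrt(n) / est.b_n * (0.6 - est.a_hat))
        med = float(np.median(vals))
        assert abs(med - 0.6) < 0.25 * 0.6


class TestLimitSimulation:
    def test_reproducible_single_draw(self, uniform_bg):
        t = setting_truth("1a")
        a = simulate_alpha_limit(t.F0, uniform_bg, (0.6, 0.8), "left_support",
                                 N=500, M=1, seed=3)
        b = simulate_alpha_limit(t.F0, uniform_bg, (0.6, 0.8), "left_support",
                                 N=500, M=1, seed=3)
        assert a.draws[0] == b.draws[0]
        assert isinstance(a, LimitSample) and a.mode == "oracle"

    def test_collapsed_interval_matches_bridge_marginal(self, uniform_bg):
        """Single-point interval: draws are a scaled Brownian-bridge marginal."""
        t = setting_truth("1a")
        x0 = 0.7
        F0x = float(t.F0(x0))
        ls = simulate_alpha_limit(t.F0, uniform_bg, (x0, x0), "left_support",
                                  N=100_000, M=10_000, seed=11)
        target = F0x * (1 - F0x) / (1 - x0) ** 2
        assert np.var(ls.draws) == pytest.approx(target, rel=0.05)

    def test_plugin_mode_uses_exact_candidates(self, uniform_bg, rng):
        e = EmpiricalCDF(rng.random(50))
        ls = simulate_alpha_limit(e, uniform_bg, (0.5, 0.8), "left_support",
                                  N=200, M=10, seed=0)
        assert ls.mode == "plugin" and ls.draws.shape == (10,)
        assert np.all(np.isfinite(ls.draws))


class TestConfidenceInterval:
    def _est(self, n=100):
        return estimate_alpha(np.linspace(0.01, 0.5, n), background("uniform"),
                              0.8, "left_support")

    def test_degenerate_draws_collapse(self):
        est = self._est()
        ls = LimitSample(draws=np.zeros(50), N=100, interval=(0.3, 0.8), mode="oracle")
        lo, hi = alpha_confidence_interval(est, ls, 0.95)
        assert lo == pytest.approx(est.alpha_hat) and hi == pytest.approx(est.alpha_hat)

    def test_symmetric_draws_center_on_estimate(self):
        from semimix import AlphaEstimate
        est = AlphaEstimate(alpha_hat=0.5, kappa0=0.8,
                            problem="left_support", n=100)
        d = np.concatenate((np.linspace(-1, 1, 101),))
        ls = LimitSample(draws=d, N=100, interval=(0.3, 0.8), mode="oracle")
        lo, hi = alpha_confidence_interval(est, ls, 0.9)
        assert (lo + hi) / 2 == pytest.approx(est.alpha_hat, abs=1e-9)

    def test_clipped_to_unit_interval(self):
        est = self._est(5)
        ls = LimitSample(draws=np.array([-100.0, 100.0] * 30), N=10,
                         interval=(0.3, 0.8), mode="oracle")
        lo, hi = alpha_confidence_interval(est, ls, 0.99)
        assert 0.0 <= lo <= hi <= 1.0

    def test_coverage_plugin_mode(self, uniform_bg):
        """Plug-in CIs cover the true proportion at roughly nominal rate."""
        rng = np.random.default_rng(7)
        n, hits, R = 2000, 0, 150
        for _ in range(R):
            s = sample_setting("1b", n, rng)
            e = EmpiricalCDF(s)
            a = estimate_alpha(e, uniform_bg, 0.8, "left_support")
            a0_est = estimate_a0(e, uniform_bg, 0.8, a)
            ls = simulate_alpha_limit(e, uniform_bg, (a0_est.a_hat, 0.8),
                                      "left_support", N=n, M=400, seed=rng)
            lo, hi = alpha_confidence_interval(a, ls, 0.95)
            hits += lo <= 0.8 <= hi
        assert 0.88 <= hits / R <= 1.0
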