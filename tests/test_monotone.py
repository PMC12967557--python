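"""Grenander fit, signal transform, Chernoff CIs, resampling, bootstrap."""

import numpy as np
import pytest

from semimix import (CHERNOFF_QUANTILES, background, bootstrap_ci,
                     chernoff_ci, chernoff_quantile_simulate, grenander_fit,
                     sample_from_fit, sample_setting, signal_density,
                     slope_estimate)
from semimix.empirical import DomainError
from semimix.monotone import DegenerateSlopeError, chernoff_two_sided_quantile


def lcm_oracle_heights(sample):
    """Brute-force least-concave-majorant left derivatives via chord maxima."""
    s = np.sort(np.asarray(sample, dtype=float))
    n = s.size
    xs = np.concatenate(([0.0], np.unique(s)))
    ys = np.searchsorted(s, xs, side="right") / n
    # LCM evaluated on the knot set by exhausting chords
    def lcm(g):
        best = -np.inf
        for i in range(xs.size):
            for j in range(xs.size):
                if xs[i] <= g <= xs[j] and xs[j] > xs[i]:
                    best = max(best, ys[i] + (ys[j] - ys[i]) * (g - xs[i])
                               / (xs[j] - xs[i]))
                elif xs[i] == g == xs[j]:
                    best = max(best, ys[i])
        return best
    return lcm


class TestGrenander:
    def test_worked_example(self):
        fit = grenander_fit([0.1, 0.2, 0.6])
        np.testing.assert_allclose(fit.knots, [0.2, 0.6])
        np.testing.assert_allclose(fit.heights, [10 / 3, 5 / 6])

    def test_single_point(self):
        fit = grenander_fit([0.5])
        np.testing.assert_allclose(fit.heights, [2.0])

    def test_equal_spacing_gives_chord_slopes(self):
        s = np.arange(1, 6) / 5.0
        fit = grenander_fit(s)
        # ECDF points lie on the diagonal: a single block of height 1
        np.testing.assert_allclose(fit.heights, [1.0])

    def test_normalisation_and_monotone_heights(self, rng):
        for _ in range(50):
            fit = grenander_fit(rng.random(int(rng.integers(1, 60))))
            assert fit.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(fit.heights) < 0)

    def test_matches_lcm_oracle(self, rng):
        for _ in range(200):
            s = rng.random(int(rng.integers(1, 50)))
            fit = grenander_fit(s)
            lcm = lcm_oracle_heights(s)
            edges = np.concatenate(([0.0], fit.knots))
            # integral of the fitted density up to each knot equals the LCM there
            csum = np.cumsum(fit.heights * np.diff(edges))
            for knot, val in zip(fit.knots, csum):
                assert val == pytest.approx(lcm(knot), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            grenander_fit([])


class TestSignalTransform:
    def test_pure_background_is_identity(self):
        fit = grenander_fit(np.linspace(0.01, 1.0, 100))
        sf = signal_density(fit, 0.7)
        # fitted density ~ 1 -> transformed density ~ 1
        assert float(sf(0.5)) == pytest.approx(1.0, abs=0.15)

    def test_worked_arithmetic(self):
        fit = grenander_fit([0.1, 0.2, 0.6])
        sf = signal_density(fit, 0.5)
        assert float(sf(0.1)) == pytest.approx(17 / 3)
        assert float(sf(0.5)) == pytest.approx(2 / 3)

    def test_truncation_at_zero(self):
        fit = grenander_fit([0.05, 0.1, 0.9, 0.95])
        sf = signal_density(fit, 0.2)
        x = np.linspace(0, 1, 101)
        assert np.all(sf(x) >= 0.0)

    def test_zero_alpha_rejected(self):
        fit = grenander_fit([0.3])
        with pytest.raises(DomainError):
            signal_density(fit, 0.0)


class TestSlope:
    def test_linear_profile_exact(self):
        class Lin:
            n = 1000
            support = (0.0, 1.0)
            def __call__(self, x):
                return 2.0 - 1.5 * np.asarray(x)
        assert slope_estimate(Lin(), 0.5, order=1) == pytest.approx(-1.5)

    def test_quadratic_second_difference(self):
        class Quad:
            n = 10_000
            support = (0.0, 1.0)
            def __call__(self, x):
                return np.asarray(x) ** 2
        assert slope_estimate(Quad(), 0.5, c=0.3, order=2) == pytest.approx(2.0)

    def test_boundary_error(self):
        fit = grenander_fit([0.2, 0.5])
        with pytest.raises(DomainError):
            slope_estimate(fit, 0.49, c=0.5, order=1)

    def test_recovers_mixture_slope_setting_2a(self, uniform_bg):
        """First derivative of the mixed density near f0' = -4 alpha0 = -2.4."""
        rng = np.random.default_rng(21)
        med = np.median([
            slope_estimate(grenander_fit(sample_setting("2a", 10_000, rng)),
                           0.3, c=0.5, order=1)
            for _ in range(60)])
        assert abs(med - (-2.4)) < 0.8


class TestChernoffCI:
    def test_tabulated_two_sided_multiplier(self):
        assert chernoff_two_sided_quantile(0.95) == pytest.approx(0.9981810993)
        assert CHERNOFF_QUANTILES[0.999] == pytest.approx(1.5166635630)

    def test_degenerate_slope_raises(self):
        class Flat:
            n = 1000
            support = (0.0, 1.0)
            def __call__(self, x):
                return np.ones_like(np.asarray(x, dtype=float))
        sf = signal_density(Flat(), 0.5)
        with pytest.raises(DegenerateSlopeError):
            chernoff_ci(sf, 0.5)

    def test_coverage_setting_2a(self, uniform_bg):
        """Pointwise CI coverage at x0 = 0.3 in the strictly-decreasing case."""
        from semimix import estimate_alpha
        from semimix.settings import setting_truth
        rng = np.random.default_rng(22)
        truth = float(setting_truth("2a").fs(0.3))
        cov, R = 0, 80
        for _ in range(R):
            s = sample_setting("2a", 1000, rng)
            a = estimate_alpha(s, uniform_bg, 0.6, "left_support")
            sf = signal_density(grenander_fit(s), min(max(a.alpha_hat, 1e-6), 1.0))
            lo, hi = chernoff_ci(sf, 0.3, c=0.5)
            cov += lo <= truth <= hi
        # reported coverage at this design point is ~0.92-0.98
        assert cov / R >= 0.85


class TestResampling:
    def test_single_block_uniform(self, rng):
        fit = grenander_fit([0.5])
        draws = sample_from_fit(fit, 5000, seed=rng)
        assert draws.min() >= 0.0 and draws.max() <= 0.5
        from scipy.stats import kstest
        assert kstest(draws, "uniform", args=(0, 0.5)).pvalue > 0.01

    def test_moment_match(self, rng):
        fit = grenander_fit(sample_setting("1a", 2000, 3))
        draws = sample_from_fit(fit, 100_000, seed=rng)
        edges = np.concatenate(([0.0], fit.knots))
        mean_true = float(np.sum(fit.weights * (edges[:-1] + edges[1:]) / 2))
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mean_true) < 3 * se


class TestBootstrapCI:
    def test_level_monotone(self, uniform_bg):
        s = sample_setting("1a", 500, 5)
        lo90, hi90 = bootstrap_ci(s, uniform_bg, 0.8, 0.3, B=200, level=0.90, seed=1)
        lo99, hi99 = bootstrap_ci(s, uniform_bg, 0.8, 0.3, B=200, level=0.99, seed=1)
        assert lo99 <= lo90 and hi99 >= hi90

    def test_outside_support_replicates_truncate_not_error(self, uniform_bg):
        s = sample_setting("1a", 200, 6)
        lo, hi = bootstrap_ci(s, uniform_bg, 0.8, 0.58, m_n=30, B=120, seed=2)
        assert np.isfinite(lo) and np.isfinite(hi)


def test_chernoff_simulator_brackets_table():
    q = chernoff_quantile_simulate(M=20_000, seed=4)
    assert q[0.95] == pytest.approx(CHERNOFF_QUANTILES[0.950], abs=0.03)
    # symmetry: median near zero
    qmed = chernoff_quantile_simulate(M=10_000, seed=5, levels=(0.5,))
    assert abs(qmed[0.5]) < 0.03
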