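"""Exactness of the candidate-point engine against dense-grid oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semimix import (DomainError, EmpiricalCDF, background, inf_ratio_left,
                     inf_ratio_right, sup_abs_centered_ratio)


def grid_inf_right(sample, bg, kappa0, step=1e-6, upper=2.0):
    sample = np.sort(np.asarray(sample, dtype=float))
    xs = np.arange(kappa0, upper, step)
    fn = np.searchsorted(sample, xs, side="right") / sample.size
    fb = np.asarray(bg.cdf(xs))
    vals = fn[fb > 0] / fb[fb > 0]
    return min(1.0, float(vals.min()))


def grid_inf_left(sample, bg, kappa0, step=1e-6, lower=-1.0):
    sample = np.sort(np.asarray(sample, dtype=float))
    xs = np.arange(lower, kappa0 + step / 2, step)
    fn = np.searchsorted(sample, xs, side="right") / sample.size
    fb = np.asarray(bg.cdf(xs))
    vals = (1 - fn[fb < 1]) / (1 - fb[fb < 1])
    return min(1.0, float(vals.min()))


class TestEcdf:
    def test_step_evaluation_and_left_limits_with_ties(self):
        e = EmpiricalCDF([0.2, 0.2, 0.5, 0.9])
        assert e(0.1) == 0.0
        assert e(0.2) == 0.5
        assert e.left_limit(0.2) == 0.0
        assert e(0.5) == 0.75
        assert e.left_limit(0.5) == 0.5
        assert e(2.0) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalCDF([])


class TestInfRatios:
    def test_worked_examples(self, uniform_bg):
        e = EmpiricalCDF([0.1, 0.7, 0.8, 0.9])
        assert inf_ratio_right(e, uniform_bg, 0.2) == pytest.approx(5 / 14)
        e2 = EmpiricalCDF([0.4])
        assert inf_ratio_right(e2, uniform_bg, 0.5) == 1.0
        e3 = EmpiricalCDF([0.1, 0.2, 0.3, 0.9])
        assert inf_ratio_left(e3, uniform_bg, 0.8) == pytest.approx(5 / 14)

    def test_all_data_beyond_kappa_gives_zero(self, uniform_bg):
        # left limit before the first jump vanishes
        e = EmpiricalCDF([0.5, 0.6])
        assert inf_ratio_right(e, uniform_bg, 0.2) == 0.0

    def test_all_data_above_kappa_left_gives_one(self, uniform_bg):
        e = EmpiricalCDF([0.7, 0.9])
        assert inf_ratio_left(e, uniform_bg, 0.5) == 1.0

    def test_domain_errors(self, uniform_bg):
        e = EmpiricalCDF([0.5])
        with pytest.raises(DomainError):
            inf_ratio_right(e, uniform_bg, -0.5)
        with pytest.raises(DomainError):
            inf_ratio_left(e, uniform_bg, 1.5)

    def test_matches_dense_grid_oracle_on_random_instances(self, uniform_bg, rng):
        for _ in range(100):
            n = int(rng.integers(1, 13))
            s = rng.random(n)
            k0 = float(rng.uniform(0.05, 0.95))
            assert inf_ratio_right(EmpiricalCDF(s), uniform_bg, k0) == pytest.approx(
                grid_inf_right(s, uniform_bg, k0, upper=1.0), abs=1e-5)
            assert inf_ratio_left(EmpiricalCDF(s), uniform_bg, k0) == pytest.approx(
                grid_inf_left(s, uniform_bg, k0, lower=0.0), abs=1e-5)

    def test_bounded_in_unit_interval(self, gaussian_bg, rng):
        for _ in range(50):
            s = rng.standard_normal(int(rng.integers(1, 10)))
            k0 = float(rng.uniform(-1, 1))
            assert 0.0 <= inf_ratio_right(EmpiricalCDF(s), gaussian_bg, k0) <= 1.0
            assert 0.0 <= inf_ratio_left(EmpiricalCDF(s), gaussian_bg, k0) <= 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=12),
           st.floats(0.05, 0.95))
    def test_infima_bounded_and_ordered(self, data, k0):
        """Infima stay in [0,1] and shrink as the search region grows."""
        bg = background("uniform")
        e = EmpiricalCDF(data)
        r = inf_ratio_right(e, bg, k0)
        l = inf_ratio_left(e, bg, k0)
        assert 0.0 <= r <= 1.0 and 0.0 <= l <= 1.0
        if k0 > 0.1:
            assert inf_ratio_right(e, bg, k0 - 0.05) <= r + 1e-12
        if k0 < 0.9:
            assert inf_ratio_left(e, bg, k0 + 0.05) <= l + 1e-12

    def test_mirror_symmetry(self, uniform_bg, rng):
        for _ in range(20):
            s = rng.random(6)
            k0 = float(rng.uniform(0.2, 0.8))
            left = inf_ratio_left(EmpiricalCDF(s), uniform_bg, k0)
            right = inf_ratio_right(EmpiricalCDF(1 - s), uniform_bg, 1 - k0)
            assert left == pytest.approx(right, abs=1e-12)


class TestSupCenteredRatio:
    def test_worked_example(self, uniform_bg):
        e = EmpiricalCDF([0.1, 0.5])
        got = sup_abs_centered_ratio(e, uniform_bg, 0.6, 0.8, "left_tail")
        assert got == pytest.approx(np.sqrt(2) * (1 / 0.6 - 1 / 0.8))

    def test_constant_ecdf_ratio_still_varies_through_background(self, uniform_bg):
        # single datum below the window: F_n = 1 there, R = 1/x
        e = EmpiricalCDF([0.05])
        got = sup_abs_centered_ratio(e, uniform_bg, 0.5, 0.6, "left_tail")
        assert got == pytest.approx(1 / 0.5 - 1 / 0.6)

    def test_degenerate_window_is_zero(self, uniform_bg):
        e = EmpiricalCDF([0.3])
        assert sup_abs_centered_ratio(e, uniform_bg, 0.5, 0.5, "left_tail") == 0.0

    def test_matches_dense_grid_oracle(self, uniform_bg, rng):
        for _ in range(100):
            n = int(rng.integers(1, 13))
            s = np.sort(rng.random(n))
            lo = float(rng.uniform(0.1, 0.5))
            hi = float(rng.uniform(lo + 0.05, 0.95))
            e = EmpiricalCDF(s)
            for side in ("left_tail", "right_tail"):
                xs = np.arange(lo, hi, 1e-6)
                fn = np.searchsorted(s, xs, side="right") / n
                if side == "left_tail":
                    r = fn / xs
                    anchor = e(hi) / hi
                else:
                    r = (1 - fn) / (1 - xs)
                    anchor = (1 - e(lo)) / (1 - lo)
                oracle = np.sqrt(n) * float(np.max(np.abs(r - anchor)))
                got = sup_abs_centered_ratio(e, uniform_bg, lo, hi, side)
                assert got == pytest.approx(oracle, abs=1e-4)
                assert got >= oracle - 1e-12  # exact sup dominates any grid
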