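"""Monotone (Grenander) estimation of the mixed and signal densities.

With a uniform background on [0, 1] and a non-increasing signal density
supported on ``[0, a0]``, the mixed density ``f0 = 1 - alpha0 + alpha0 f_s``
is non-increasing with a plateau at ``1 - alpha0``.  Its nonparametric MLE is
the Grenander estimator: the left derivative of the least concave majorant
(LCM) of the ECDF, a non-increasing step function.  The signal density is
recovered by the plug-in transform ``(f_hat - 1 + alpha_hat)/alpha_hat`` and
truncation at zero.

Pointwise inference at a point where the mixed density has a strictly
negative derivative follows cube-root asymptotics: the centred estimator
converges at rate ``n^{1/3}`` to a scaled Chernoff limit (the argmax of a
two-sided Brownian motion minus a parabola), whose quantiles ship as a
lookup table.  Where the density is locally flat the limit changes and the
package falls back on the m-out-of-n bootstrap, resampling from the fitted
step density (a finite mixture of uniform blocks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .empirical import BackgroundModel, DomainError, EmpiricalCDF
from .estimate import default_bn, estimate_alpha

__all__ = [
    "MonotoneDensityFit", "SignalDensityFit", "CHERNOFF_QUANTILES",
    "grenander_fit", "signal_density", "slope_estimate", "chernoff_ci",
    "chernoff_two_sided_quantile", "sample_from_fit", "bootstrap_ci",
    "chernoff_quantile_simulate", "DegenerateSlopeError",
]


class DegenerateSlopeError(RuntimeError):
    """Zero slope estimate: the flat-region limit is suspected; use the bootstrap."""


#: Two-sided Brownian motion minus parabola: argmax-location quantiles.
CHERNOFF_QUANTILES = {
    0.900: 0.6642351969,
    0.950: 0.8450811902,
    0.975: 0.9981810993,
    0.990: 1.1715343420,
    0.995: 1.2866587967,
    0.999: 1.5166635630,
}


@dataclass(frozen=True)
class MonotoneDensityFit:
    """Non-increasing step density: height ``c_i`` on ``(tau_{i-1}, tau_i]``."""

    knots: np.ndarray        # tau_1 < ... < tau_p, block right edges
    heights: np.ndarray      # c_1 > ... > c_p > 0
    n: int
    shape: str = "monotone"

    @property
    def weights(self) -> np.ndarray:
        edges = np.concatenate(([0.0], self.knots))
        return self.heights * np.diff(edges)

    @property
    def support(self) -> tuple:
        return (0.0, float(self.knots[-1]))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.knots, x, side="left")
        idx = np.clip(idx, 0, self.knots.size - 1)
        out = self.heights[idx]
        return np.where((x >= 0.0) & (x <= self.knots[-1]), out, 0.0)


@dataclass(frozen=True)
class SignalDensityFit:
    """Signal density via the truncated plug-in transform of a mixed-density fit."""

    base: object             # MonotoneDensityFit or ConvexDensityFit
    alpha_hat: float

    def __call__(self, x):
        a = self.alpha_hat
        return np.maximum((np.asarray(self.base(x)) - 1.0 + a) / a, 0.0)


def grenander_fit(sample) -> MonotoneDensityFit:
    """Left derivative of the least concave majorant of the ECDF on [0, X_(n)].

    Computed as the upper concave hull of the points ``(0,0), (X_(j), F_n(X_(j)))``
    by a monotone-chain scan (equivalent to pooling adjacent violators on the
    jump increments); exact and O(n) after sorting.
    """
    ecdf = sample if isinstance(sample, EmpiricalCDF) else EmpiricalCDF(sample)
    pts, f_plus, _ = ecdf.unique_points()
    if pts[0] <= 0.0 and pts.size == 1:
        raise DomainError("degenerate sample at a single non-positive point")
    xs = np.concatenate(([0.0], pts))
    ys = np.concatenate(([0.0], f_plus))
    # upper concave hull, left to right: keep slopes strictly decreasing
    hull = [0]
    for i in range(1, xs.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # slope(j,k) <= slope(k,i) -> k is below the majorant, drop it
            if (ys[k] - ys[j]) * (xs[i] - xs[k]) <= (ys[i] - ys[k]) * (xs[k] - xs[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    hx = xs[hull]
    hy = ys[hull]
    heights = np.diff(hy) / np.diff(hx)
    return MonotoneDensityFit(knots=hx[1:], heights=heights, n=ecdf.n)


def signal_density(base_fit, alpha_hat) -> SignalDensityFit:
    """Truncated plug-in transform ``((f_hat - 1 + alpha)/alpha) v 0``."""
    if hasattr(alpha_hat, "alpha_hat"):
        alpha_hat = alpha_hat.alpha_hat
    if not 0.0 < alpha_hat <= 1.0:
        raise DomainError("alpha_hat must lie in (0, 1] for the signal transform")
    return SignalDensityFit(base=base_fit, alpha_hat=float(alpha_hat))


def _delta_n(n: int, c: float, order: int) -> float:
    if order == 1:
        return c * (math.log(n)) ** (2.0 / 3.0) * n ** (-1.0 / 3.0)
    if order == 2:
        return c * (math.log(n)) ** (2.0 / 5.0) * n ** (-1.0 / 5.0)
    raise ValueError("order must be 1 or 2")


def slope_estimate(fit, x0: float, c: float = 0.5, order: int = 1) -> float:
    """Symmetric difference quotient of the fitted density at ``x0``.

    ``order=1``: first derivative with bandwidth ``c (log n)^{2/3} n^{-1/3}``;
    ``order=2``: second derivative with bandwidth ``c (log n)^{2/5} n^{-1/5}``.
    """
    d = _delta_n(fit.n, c, order)
    lo, hi = fit.support
    if x0 - d < lo or x0 + d > hi:
        raise DomainError(f"slope window [{x0 - d:.4g}, {x0 + d:.4g}] leaves "
                          f"the fitted support [{lo:.4g}, {hi:.4g}]")
    if order == 1:
        return float((fit(x0 + d) - fit(x0 - d)) / (2.0 * d))
    return float((fit(x0 + d) + fit(x0 - d) - 2.0 * fit(x0)) / d ** 2)


def chernoff_two_sided_quantile(level: float) -> float:
    """Two-sided quantile via the (1+level)/2 table row (the limit is symmetric)."""
    key = round((1.0 + level) / 2.0, 3)
    try:
        return CHERNOFF_QUANTILES[key]
    except KeyError:
        raise ValueError(f"no tabulated quantile for two-sided level {level}; "
                         f"available rows: {sorted(CHERNOFF_QUANTILES)}") from None


def chernoff_ci(signal_fit: SignalDensityFit, x0: float, c: float = 0.5,
                level: float = 0.95) -> tuple:
    """Pointwise CI for the signal density under cube-root asymptotics.

    Half-width ``q * n^{-1/3} |4 f_hat(x0) d_hat(x0)|^{1/3} / alpha_hat`` with
    ``q`` the two-sided Chernoff quantile and ``d_hat`` the first-order slope
    estimate of the mixed density.  Requires a locally strictly decreasing
    density; a vanishing slope estimate points to the flat-region regime.
    """
    base = signal_fit.base
    d_hat = slope_estimate(base, x0, c=c, order=1)
    if d_hat == 0.0:
        raise DegenerateSlopeError(
            "slope estimate is zero at x0: flat region suspected; "
            "use bootstrap_ci instead")
    q = chernoff_two_sided_quantile(level)
    n = base.n
    half = q * n ** (-1.0 / 3.0) / signal_fit.alpha_hat * abs(
        4.0 * float(base(x0)) * d_hat) ** (1.0 / 3.0)
    center = float(signal_fit(x0))
    return (center - half, center + half)


def sample_from_fit(fit, m: int, seed=None) -> np.ndarray:
    """Draw from a fitted mixture density (monotone blocks or convex triangles).

    A multinomial pick over mixture weights, then a uniform draw on the block
    (monotone) or an inverse-CDF draw from the triangular component
    ``2(tau - x)_+ / tau^2`` (convex).
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    rng = np.random.default_rng(seed)
    if fit.shape == "monotone":
        w = fit.weights
        edges = np.concatenate(([0.0], fit.knots))
        comp = rng.choice(w.size, size=m, p=w / w.sum())
        return np.sort(rng.uniform(edges[comp], edges[comp + 1]))
    if fit.shape == "convex":
        w = np.asarray(fit.weights, dtype=float)
        comp = rng.choice(w.size, size=m, p=w / w.sum())
        tau = np.asarray(fit.knots, dtype=float)[comp]
        return np.sort(tau * (1.0 - np.sqrt(rng.random(m))))
    raise ValueError(f"cannot sample from fit with shape {fit.shape!r}")


def bootstrap_ci(sample, bg: BackgroundModel, kappa0: float, x0: float,
                 m_n: int | None = None, B: int = 500, level: float = 0.95,
                 shape: str = "monotone", seed=None, c: float = 0.5) -> tuple:
    """m-out-of-n bootstrap CI for the signal density at ``x0``.

    Fits the mixed density under the requested shape, then draws ``B``
    resamples of size ``m_n`` from the fitted density; each resample
    re-estimates the mixing proportion (same ``kappa0``), refits the shape and
    evaluates the transformed signal density at ``x0``.  Quantiles of
    ``sqrt(m_n) (f*_s(x0) - f_hat_s(x0))`` are inverted on the ``sqrt(n)``
    scale.  Undersampling (``m_n = o(n)``) restores bootstrap consistency in
    the non-standard flat-region regimes; defaults are ``n^{2/3}`` (monotone)
    and ``n^{4/5}`` (convex).
    """
    from .convex import convex_lse_fit  # local import to avoid a cycle

    ecdf = sample if isinstance(sample, EmpiricalCDF) else EmpiricalCDF(sample)
    n = ecdf.n
    if m_n is None:
        m_n = int(n ** (2.0 / 3.0)) if shape == "monotone" else int(n ** 0.8)
    if not 1 <= m_n < n:
        raise ValueError("m_n must satisfy 1 <= m_n < n")
    if B < 100:
        raise ValueError("B must be at least 100")
    if shape == "monotone":
        fitter = grenander_fit
    elif shape == "convex":
        fitter = convex_lse_fit
    else:
        raise ValueError("shape must be 'monotone' or 'convex'")
    rng = np.random.default_rng(seed)
    alpha = estimate_alpha(ecdf, bg, kappa0, "left_support")
    base = fitter(ecdf.values)
    f_s = signal_density(base, alpha)
    center = float(f_s(x0))
    stats = np.empty(B)
    for b in range(B):
        star = sample_from_fit(base, m_n, seed=rng)
        alpha_star = estimate_alpha(star, bg, kappa0, "left_support")
        base_star = fitter(star)
        a_star = min(max(alpha_star.alpha_hat, 1e-12), 1.0)
        val = max((float(base_star(x0)) - 1.0 + a_star) / a_star, 0.0)
        stats[b] = math.sqrt(m_n) * (val - center)
    beta = 1.0 - level
    q_lo = float(np.quantile(stats, beta / 2.0))
    q_hi = float(np.quantile(stats, 1.0 - beta / 2.0))
    rn = math.sqrt(n)
    return (center - q_hi / rn, center - q_lo / rn)


def chernoff_quantile_simulate(M: int = 50_000, grid_halfwidth: float = 2.5,
                               grid_step: float = 0.01, seed=None,
                               levels=(0.900, 0.950, 0.975, 0.990, 0.995, 0.999),
                               chunk: int = 2000):
    """Monte-Carlo estimate of argmax-location quantiles (validation tool).

    Simulates the argmax over ``[-h, h]`` of a discretised two-sided Brownian
    motion minus ``t^2`` and reports empirical quantiles of the location.  The
    tabulated constants remain authoritative; this exists to validate them.
    """
    if grid_halfwidth < 2.0:
        raise ValueError("grid must cover at least [-2, 2]")
    rng = np.random.default_rng(seed)
    k = int(round(grid_halfwidth / grid_step))
    t_pos = np.arange(1, k + 1) * grid_step
    drift_pos = t_pos ** 2
    locs = np.empty(M)
    done = 0
    while done < M:
        b = min(chunk, M - done)
        # two independent wings pinned at W(0) = 0
        right = np.cumsum(rng.standard_normal((b, k)) * math.sqrt(grid_step), axis=1) - drift_pos
        left = np.cumsum(rng.standard_normal((b, k)) * math.sqrt(grid_step), axis=1) - drift_pos
        vals = np.concatenate((left[:, ::-1], np.zeros((b, 1)), right), axis=1)
        idx = np.argmax(vals, axis=1)
        locs[done:done + b] = (idx - k) * grid_step
        done += b
    return {lv: float(np.quantile(locs, lv)) for lv in levels}
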