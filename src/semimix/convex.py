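"""Convex-decreasing least-squares density estimation via support reduction.

A convex, non-increasing density on (0, 1] that vanishes at the end of its
support is a mixture of triangular components ``k_tau(x) = 2 (tau - x)_+ /
tau^2``.  The least-squares estimator minimises ``Q(f) = 1/2 int f^2 -
int f dF_n`` over that cone.  In mixture coordinates ``f = sum c_i k_{tau_i}``
this is a non-negative quadratic programme with Gram matrix

    A_ij = (2 max(ti,tj) - 2 min(ti,tj)/3) / max(ti,tj)^2

and loadings ``b_i = (1/n) sum_j k_{tau_i}(X_j)``.  The support-reduction
algorithm keeps a small active set of kink locations: it repeatedly adds the
candidate with the most negative directional derivative, re-solves the
restricted non-negative problem, and drops zero-weight components, stopping
when no direction improves by more than ``tol``.  At the optimum the fit
integrates to one (scale optimality along the cone's rays), so the weights
are mixture proportions and the fit can be resampled exactly.

The pointwise limit law of the LSE at a point of strict convexity involves the
second derivative at zero of the convex envelope of an integrated Brownian
motion plus ``t^4``; its quantiles ship as a lookup table, and a scaled
simulator (fitting a known quadratic-decay density at its midpoint) exists to
validate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import nnls

from .empirical import DomainError, EmpiricalCDF
from .monotone import slope_estimate

__all__ = ["ConvexDensityFit", "HPP_QUANTILES", "convex_lse_fit", "convex_ci",
           "hpp_quantile_simulate", "LinearRegionError"]


class LinearRegionError(RuntimeError):
    """Non-positive curvature estimate: the linear-region limit is suspected."""


#: Quantiles of the convex-LSE pointwise limit (second derivative at zero of
#: the convex envelope of integrated two-sided Brownian motion plus t^4).
HPP_QUANTILES = {
    0.025: -2.437220,
    0.050: -2.016842,
    0.100: -1.572602,
    0.900: 1.585226,
    0.950: 1.977245,
    0.975: 2.336658,
    0.990: 2.591252,
    0.995: 2.736833,
    0.999: 3.090453,
}


@dataclass(frozen=True)
class ConvexDensityFit:
    """Piecewise-linear convex decreasing density ``sum c_i 2(tau_i - x)_+/tau_i^2``."""

    knots: np.ndarray        # kink locations tau_1 < ... < tau_p
    weights: np.ndarray      # mixture weights c_i > 0
    n: int
    objective: float         # value of Q at the fit
    gap: float               # most negative directional derivative at exit
    iterations: int
    shape: str = "convex"

    @property
    def support(self) -> tuple:
        return (0.0, float(self.knots[-1]))

    def __call__(self, x):
        shape = np.shape(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        tau = self.knots[:, None]
        vals = 2.0 * np.clip(tau - x[None, :], 0.0, None) / tau ** 2
        out = np.where(x >= 0.0, self.weights @ vals, 0.0)
        return out.reshape(shape) if shape else float(out[0])


def _gram_columns(taus: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Columns of the triangular-kernel Gram matrix for the active knots."""
    ti = np.minimum(taus[:, None], active[None, :])
    tj = np.maximum(taus[:, None], active[None, :])
    return (2.0 * tj - (2.0 / 3.0) * ti) / tj ** 2


def _loadings(taus: np.ndarray, sorted_sample: np.ndarray) -> np.ndarray:
    """``(1/n) sum_j 2 (tau - X_j)_+ / tau^2`` via prefix sums."""
    n = sorted_sample.size
    cnt = np.searchsorted(sorted_sample, taus, side="left")
    csum = np.concatenate(([0.0], np.cumsum(sorted_sample)))
    return 2.0 * (taus * cnt - csum[cnt]) / (taus ** 2 * n)


def _restricted_nnls(active: np.ndarray, b_act: np.ndarray) -> np.ndarray:
    """Exact solution of ``min 1/2 c'Ac - b'c, c >= 0`` on the active set."""
    A = _gram_columns(active, active)
    # A is a Gram matrix of linearly independent kernels -> PD Cholesky
    L = cholesky(A, lower=True)
    h = solve_triangular(L, b_act, lower=True)
    c, _ = nnls(L.T, h)
    return c


def convex_lse_fit(sample, tol: float = 1e-8, max_iter: int = 500,
                   refine_grid: int = 256) -> ConvexDensityFit:
    """Support-reduction least-squares fit of a convex decreasing density.

    Candidate kink locations are the observed values together with a
    ``refine_grid``-point equispaced refinement of (0, 1] (kinks of the exact
    LSE fall between observations).  Starts from the best single component;
    stops when every candidate direction has derivative ``>= -tol``.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    if x.size < 1:
        raise DomainError("empty sample")
    if x[0] < 0.0:
        raise DomainError("sample must be non-negative")
    # The fitted support may extend beyond the data maximum (the estimator
    # integrates to one only on an unconstrained cone); extend adaptively.
    hi = 1.5 * max(1.0, float(x[-1]))
    for _ in range(8):
        fit = _fit_on_range(x, hi, tol, max_iter, refine_grid)
        if fit.knots[-1] < 0.995 * hi:
            return fit
        hi *= 2.0
    return fit


def _fit_on_range(x: np.ndarray, hi: float, tol: float, max_iter: int,
                  refine_grid: int) -> "ConvexDensityFit":
    taus = np.unique(np.concatenate((
        x[x > 0.0], np.linspace(hi / refine_grid, hi, refine_grid))))
    b = _loadings(taus, x)
    diag = (4.0 / 3.0) / taus
    # best single component: maximises b^2/A_tt with positive weight
    scores = np.where(b > 0.0, b * b / diag, -np.inf)
    if not np.isfinite(scores).any():
        raise DomainError("no candidate component has positive loading")
    active = np.array([taus[int(np.argmax(scores))]])
    c = np.array([b[int(np.argmax(scores))] / diag[int(np.argmax(scores))]])
    gap = np.inf
    for it in range(1, max_iter + 1):
        grad = _gram_columns(taus, active) @ c - b
        j = int(np.argmin(grad))
        gap = float(grad[j])
        if gap >= -tol:
            break
        if taus[j] not in active:
            active = np.sort(np.append(active, taus[j]))
        c = _restricted_nnls(active, _loadings(active, x))
        keep = c > 0.0
        active, c = active[keep], c[keep]
        if active.size == 0:
            raise RuntimeError("support reduction dropped all components")
    else:
        raise RuntimeError(f"support reduction did not converge in {max_iter} "
                           f"iterations (gap {gap:.3e})")
    A_act = _gram_columns(active, active)
    b_act = _loadings(active, x)
    obj = 0.5 * float(c @ A_act @ c) - float(c @ b_act)
    return ConvexDensityFit(knots=active, weights=c, n=x.size, objective=obj,
                            gap=gap, iterations=it)


def convex_ci(signal_fit, x0: float, c: float = 0.5, level: float = 0.95) -> tuple:
    """Pointwise CI for the signal density under the strict-convexity limit.

    Offsets ``|q_{(1-level)/2}|`` (lower) and ``q_{(1+level)/2}`` (upper) from
    the tabulated limit quantiles, scaled by
    ``n^{-2/5} (f_hat(x0)^2 d_hat(x0)/24)^{1/5} / alpha_hat`` with ``d_hat``
    the second-order curvature estimate of the mixed density.
    """
    base = signal_fit.base
    d_hat = slope_estimate(base, x0, c=c, order=2)
    if d_hat <= 0.0:
        raise LinearRegionError(
            "curvature estimate is non-positive at x0: linear region "
            "suspected; use bootstrap_ci(shape='convex') instead")
    lo_key = round((1.0 - level) / 2.0, 3)
    hi_key = round((1.0 + level) / 2.0, 3)
    if lo_key not in HPP_QUANTILES or hi_key not in HPP_QUANTILES:
        raise ValueError(f"no tabulated quantiles for level {level}")
    scale = base.n ** (-0.4) / signal_fit.alpha_hat * (
        float(base(x0)) ** 2 * d_hat / 24.0) ** 0.2
    center = float(signal_fit(x0))
    return (center - abs(HPP_QUANTILES[lo_key]) * scale,
            center + HPP_QUANTILES[hi_key] * scale)


def hpp_quantile_simulate(N: int = 5000, M: int = 300, seed=None,
                          levels=(0.05, 0.5, 0.95)):
    """Scaled Monte-Carlo estimate of the convex-LSE limit quantiles.

    Fits the convex LSE to samples from the quadratic-decay density
    ``3 (1 - x)^2`` on [0, 1] and evaluates the centred, ``N^{2/5}``-scaled
    error at the midpoint, whose limit is the tabulated law:
    ``(64/9)^{1/5} N^{2/5} (g_N(1/2) - 3/4)``.  Returns empirical quantiles.
    """
    if N < 1000 or M < 100:
        raise ValueError("requires N >= 1000 and M >= 100")
    rng = np.random.default_rng(seed)
    scale = (64.0 / 9.0) ** 0.2 * N ** 0.4
    draws = np.empty(M)
    for m in range(M):
        g = rng.beta(1.0, 3.0, size=N)
        fit = convex_lse_fit(g)
        draws[m] = scale * (float(fit(0.5)) - 0.75)
    return {lv: float(np.quantile(draws, lv)) for lv in levels}, draws
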