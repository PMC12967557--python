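"""Mixing-proportion and support-endpoint estimation, with limit-law simulation.

For the mixture ``F0 = (1 - alpha0) Fb + alpha0 Fs`` with known background
``Fb`` and signal support starting at ``a0`` (``right_support``) or ending at
``a0`` (``left_support``), and a user bound ``kappa0`` on the signal-free
region, the mixing proportion is estimated by the constrained ECDF-ratio

    alpha_hat = 1 - inf_{x >= kappa0} F_n(x)/F_b(x)          (right_support)
    alpha_hat = 1 - inf_{x <= kappa0} (1-F_n(x))/(1-F_b(x))  (left_support)

which converges at the parametric sqrt(n) rate.  The endpoint ``a0`` is then
estimated by thresholding the centred ECDF at ``alpha_hat * b_n / sqrt(n)``
with a slowly diverging sequence ``b_n`` (default ``log log n``).  The
limiting law of ``sqrt(n) (alpha_hat - alpha0)`` — the negative infimum of a
Brownian bridge composed with ``F0`` over the signal-free window, scaled by
the background CDF — is simulated with a uniform-ECDF surrogate bridge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .empirical import (BackgroundModel, DomainError, EmpiricalCDF,
                        inf_ratio_left, inf_ratio_right, _interval_candidates)

__all__ = [
    "AlphaEstimate", "ChangepointEstimate", "LimitSample",
    "estimate_alpha", "estimate_a0", "default_bn",
    "simulate_alpha_limit", "alpha_confidence_interval",
]


@dataclass(frozen=True)
class AlphaEstimate:
    alpha_hat: float
    kappa0: float
    problem: str
    n: int


@dataclass(frozen=True)
class ChangepointEstimate:
    a_hat: float
    b_n: float
    threshold: float
    attained: bool


@dataclass(frozen=True)
class LimitSample:
    draws: np.ndarray
    N: int
    interval: tuple
    mode: str


def _as_ecdf(sample):
    return sample if isinstance(sample, EmpiricalCDF) else EmpiricalCDF(sample)


def estimate_alpha(sample, bg: BackgroundModel, kappa0: float, problem: str) -> AlphaEstimate:
    """Constrained ECDF-ratio estimator of the mixing proportion."""
    ecdf = _as_ecdf(sample)
    if problem == "right_support":
        inf_val = inf_ratio_right(ecdf, bg, kappa0)
    elif problem == "left_support":
        inf_val = inf_ratio_left(ecdf, bg, kappa0)
    else:
        raise ValueError("problem must be 'right_support' or 'left_support'")
    return AlphaEstimate(alpha_hat=1.0 - inf_val, kappa0=float(kappa0),
                         problem=problem, n=ecdf.n)


def default_bn(n: int) -> float:
    """Threshold sequence ``b_n = log log n`` (0.1 for tiny n where it is <= 0)."""
    val = math.log(math.log(n)) if n > 1 else 0.0
    return val if val > 0.0 else 0.1


def estimate_a0(sample, bg: BackgroundModel, kappa0: float, alpha_hat,
                b_n: float | None = None) -> ChangepointEstimate:
    """Support-endpoint estimator via ECDF thresholding.

    ``right_support``: largest x at which the centred ECDF
    ``F_n(x) - (1-alpha)F_b(x)`` still sits below ``alpha * b_n / sqrt(n)``;
    ``left_support``: mirrored.  The qualifying set's extremum always sits at a
    data point (constancy pieces of the ECDF make the criterion monotone
    within pieces), so the scan is exact.
    """
    if isinstance(alpha_hat, AlphaEstimate):
        problem = alpha_hat.problem
        if alpha_hat.kappa0 != kappa0:
            raise ValueError("kappa0 differs from the one used for alpha_hat")
        alpha = alpha_hat.alpha_hat
    else:
        raise TypeError("alpha_hat must be an AlphaEstimate "
                        "(carries the problem orientation)")
    ecdf = _as_ecdf(sample)
    n = ecdf.n
    if b_n is None:
        b_n = default_bn(n)
    if b_n <= 0:
        raise ValueError("b_n must be positive")
    alpha_c = min(max(alpha, 1e-12), 1.0)  # clipped inside the threshold
    t = alpha_c * b_n / math.sqrt(n)
    if alpha_c <= t:
        raise DomainError("threshold exceeds alpha_hat (b_n >= sqrt(n)): "
                          "the qualifying set is unbounded")
    pts, f_plus, f_minus = ecdf.unique_points()
    if problem == "right_support":
        mask = pts > kappa0
        crit = f_minus[mask] - (1.0 - alpha_c) * np.asarray(bg.cdf(pts[mask]), dtype=float)
        ok = pts[mask][crit <= t]
        if ok.size:
            return ChangepointEstimate(float(ok.max()), b_n, t, True)
    else:
        mask = pts < kappa0
        crit = (1.0 - f_plus[mask]) - (1.0 - alpha_c) * (1.0 - np.asarray(bg.cdf(pts[mask]), dtype=float))
        ok = pts[mask][crit <= t]
        if ok.size:
            return ChangepointEstimate(float(ok.min()), b_n, t, True)
    return ChangepointEstimate(float(kappa0), b_n, t, False)


# ---------------------------------------------------------------------------
# Limit-law simulation
# ---------------------------------------------------------------------------

def _surrogate_bridge_values(sorted_uniforms: np.ndarray, t: np.ndarray) -> np.ndarray:
    """``sqrt(N) (G_N(t) - t)`` for a sorted uniform sample (one draw)."""
    N = sorted_uniforms.size
    counts = np.searchsorted(sorted_uniforms, t, side="right")
    return math.sqrt(N) * (counts / N - t)


def simulate_alpha_limit(H, bg: BackgroundModel, interval, problem: str,
                         N: int, M: int = 1000, seed=None,
                         grid_points: int = 2048) -> LimitSample:
    """Monte-Carlo draws of the limiting law of ``sqrt(n)(alpha_hat - alpha0)``.

    Each draw builds a surrogate Brownian bridge from ``N`` fresh uniforms and
    takes the negative infimum over ``interval`` of the bridge composed with
    ``H`` (a CDF evaluator or an :class:`EmpiricalCDF`), scaled by the
    background CDF (``right_support``) or survival (``left_support``).  For an
    ECDF argument the infimum is exact over the candidate set; for a smooth
    CDF a fixed grid of ``grid_points`` points plus endpoints is used.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if N < 1 or M < 1:
        raise ValueError("N and M must be positive")
    rng = np.random.default_rng(seed)
    if isinstance(H, EmpiricalCDF):
        if lo >= hi:
            x = np.array([lo])
            h = H(x)
        else:
            x, h, _ = _interval_candidates(H, lo, hi)
        mode = "plugin"
    else:
        if lo >= hi:
            x = np.array([lo])
        else:
            x = np.concatenate(([lo], np.linspace(lo, hi, grid_points), [hi]))
        h = np.asarray(H(x), dtype=float)
        mode = "oracle"
    if problem == "right_support":
        den = np.asarray(bg.cdf(x), dtype=float)
        t_eval = np.clip(h, 0.0, 1.0)
        if np.any(den <= 0.0):
            raise DomainError("background CDF vanishes on the interval")
    elif problem == "left_support":
        den = 1.0 - np.asarray(bg.cdf(x), dtype=float)
        t_eval = np.clip(1.0 - h, 0.0, 1.0)
        if np.any(den <= 0.0):
            raise DomainError("background survival vanishes on the interval")
    else:
        raise ValueError("problem must be 'right_support' or 'left_support'")
    draws = np.empty(M)
    for m in range(M):
        u = np.sort(rng.random(N))
        bridge = _surrogate_bridge_values(u, t_eval)
        draws[m] = -np.min(bridge / den)
    return LimitSample(draws=draws, N=N, interval=(lo, hi), mode=mode)


def alpha_confidence_interval(alpha_est: AlphaEstimate, limit_sample: LimitSample,
                              level: float = 0.95) -> tuple:
    """Quantile-inversion confidence interval for the mixing proportion.

    ``[alpha_hat - q_{1-beta/2}/sqrt(n), alpha_hat - q_{beta/2}/sqrt(n)]``
    intersected with [0, 1], with empirical quantiles of the limit draws.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if limit_sample.draws.size == 0:
        raise ValueError("limit sample is empty")
    beta = 1.0 - level
    q_hi = float(np.quantile(limit_sample.draws, 1.0 - beta / 2.0))
    q_lo = float(np.quantile(limit_sample.draws, beta / 2.0))
    rn = math.sqrt(alpha_est.n)
    lo = max(0.0, alpha_est.alpha_hat - q_hi / rn)
    hi = min(1.0, alpha_est.alpha_hat - q_lo / rn)
    return (lo, hi)
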