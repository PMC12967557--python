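"""Testing a candidate search bound kappa0 and selecting one from a grid.

Whether a user-supplied ``kappa0`` really lies inside the signal-free region
(``kappa0 <= a0`` for a right-supported signal, ``kappa0 >= a0`` for a
left-supported one) is testable: under the null the ECDF/background ratio is
flat on the signal-free side, so the scaled sup-distance of the ratio from its
value at the anchor has a Brownian-bridge limit.  Critical values are
simulated with a uniform-ECDF surrogate bridge.

Two compositions of the surrogate are available.  ``composition='ecdf'``
composes the bridge with the sample's own ECDF — the direct plug-in recipe.
``composition='null'`` composes it with the fitted null mixture CDF (the
background rescaled to the ratio level observed at a reference point in the
signal-free region).  Both are asymptotically exact under the null; the null
composition retains power at windows far inside the signal support, where the
ECDF carries signal mass that would otherwise inflate the critical value, and
is therefore used by the grid search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .empirical import (BackgroundModel, DomainError, EmpiricalCDF,
                        _interval_candidates, sup_abs_centered_ratio)
from .estimate import _surrogate_bridge_values

__all__ = ["TestResult", "KappaEstimate", "NoValidKappaError",
           "simulate_test_quantile", "test_kappa", "search_kappa",
           "mc_quantile"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    quantile: float
    beta: float
    M: int
    accepted: bool
    window: tuple
    side: str
    untestable: bool = False


@dataclass(frozen=True)
class KappaEstimate:
    kappa_hat: float
    grid: np.ndarray
    h0: float
    per_kappa: list


class NoValidKappaError(RuntimeError):
    """No grid point was accepted; carries per-point diagnostics."""

    def __init__(self, per_kappa):
        super().__init__("no kappa in the grid was accepted by the test")
        self.per_kappa = per_kappa


def mc_quantile(draws: np.ndarray, beta: float) -> float:
    """Order-(1-beta) Monte-Carlo quantile: the ceil((1-beta)(M+1)) order stat.

    The (M+1) convention makes the simulated test conservative and returns the
    sample maximum whenever the requested order exceeds M/(M+1).
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    M = draws.size
    rank = min(M, int(math.ceil((1.0 - beta) * (M + 1))))
    return float(draws[rank - 1])


# ---------------------------------------------------------------------------
# Surrogate sup-statistic draws
# ---------------------------------------------------------------------------

def _sup_draws_ecdf(ecdf: EmpiricalCDF, bg: BackgroundModel, window, side,
                    uniforms: np.ndarray) -> np.ndarray:
    """Sup draws with the bridge composed with the sample ECDF (plug-in)."""
    lo, hi = float(window[0]), float(window[1])
    x, f, _ = _interval_candidates(ecdf, lo, hi)
    if side == "left_tail":
        den = np.asarray(bg.cdf(x), dtype=float)
        anchor_t, anchor_den = float(ecdf(hi)), float(bg.cdf(hi))
    else:
        den = 1.0 - np.asarray(bg.cdf(x), dtype=float)
        anchor_t, anchor_den = float(ecdf(lo)), 1.0 - float(bg.cdf(lo))
    t_eval = np.concatenate((f, [anchor_t]))
    out = np.empty(uniforms.shape[0])
    for m in range(uniforms.shape[0]):
        b = _surrogate_bridge_values(uniforms[m], t_eval)
        out[m] = np.max(np.abs(b[:-1] / den - b[-1] / anchor_den))
    return out


def _sup_draws_null(bg: BackgroundModel, window, side, uniforms: np.ndarray,
                    level: float) -> np.ndarray:
    """Sup draws with the bridge composed with the fitted null mixture CDF.

    ``level`` is the null ratio level: ``F0 = level * Fb`` on the window for
    the left tail, ``1 - F0 = level * (1 - Fb)`` for the right tail.  Between
    jumps of the uniform ECDF the process is monotone in the composed time, so
    the sup is evaluated exactly at jump points (both sides) and endpoints.
    """
    lo, hi = float(window[0]), float(window[1])
    N = uniforms.shape[1]
    rn = math.sqrt(N)
    if side == "left_tail":
        t_lo, t_hi = level * float(bg.cdf(lo)), level * float(bg.cdf(hi))
    else:
        t_lo = 1.0 - level * (1.0 - float(bg.cdf(lo)))
        t_hi = 1.0 - level * (1.0 - float(bg.cdf(hi)))
    out = np.empty(uniforms.shape[0])
    for m in range(uniforms.shape[0]):
        u = uniforms[m]
        i0, i1 = np.searchsorted(u, [t_lo, t_hi])
        tj = u[i0:i1]
        ts = np.concatenate(([t_lo], tj, tj, [t_hi]))
        Gs = np.concatenate(([i0], np.arange(i0, i1) + 1.0,
                             np.arange(i0, i1), [i1])) / N
        if side == "left_tail":
            vals = rn * (Gs - ts) * level / ts
            anchor = rn * (i1 / N - t_hi) * level / t_hi
        else:
            vals = rn * (Gs - ts) * level / (1.0 - ts)
            anchor = rn * (i0 / N - t_lo) * level / (1.0 - t_lo)
        out[m] = np.max(np.abs(vals - anchor))
    return out


def null_ratio_level(ecdf: EmpiricalCDF, bg: BackgroundModel, x_ref: float,
                     side: str) -> float:
    """Observed ratio level at a reference point in the signal-free region."""
    if side == "left_tail":
        return float(ecdf(x_ref)) / float(bg.cdf(x_ref))
    return (1.0 - float(ecdf(x_ref))) / (1.0 - float(bg.cdf(x_ref)))


def simulate_test_quantile(ecdf, bg: BackgroundModel, window, side: str,
                           M: int = 1000, beta: float = 0.05, seed=None,
                           uniforms: np.ndarray | None = None,
                           composition: str = "ecdf",
                           null_level: float | None = None) -> float:
    """Simulated (1-beta) critical value of the sup statistic.

    Each of ``M`` draws builds a surrogate bridge from ``n`` fresh uniforms,
    composes it with the sample ECDF (``composition='ecdf'``) or the fitted
    null mixture CDF (``composition='null'``), and takes the exact sup over
    the window.  Pre-generated sorted uniforms may be passed to share draws
    across windows.
    """
    if not isinstance(ecdf, EmpiricalCDF):
        ecdf = EmpiricalCDF(ecdf)
    lo, hi = float(window[0]), float(window[1])
    if side == "left_tail":
        if float(bg.cdf(lo)) <= 0.0:
            raise DomainError("F_b(lo) must be positive for side='left_tail'")
    elif side == "right_tail":
        if float(bg.cdf(hi)) >= 1.0:
            raise DomainError("F_b(hi) must be below 1 for side='right_tail'")
    else:
        raise ValueError("side must be 'left_tail' or 'right_tail'")
    if uniforms is None:
        if M < 50:
            raise ValueError("M must be at least 50")
        rng = np.random.default_rng(seed)
        uniforms = np.sort(rng.random((M, ecdf.n)), axis=1)
    if lo >= hi:
        return 0.0
    if composition == "ecdf":
        draws = _sup_draws_ecdf(ecdf, bg, window, side, uniforms)
    elif composition == "null":
        if null_level is None:
            anchor = hi if side == "left_tail" else lo
            null_level = null_ratio_level(ecdf, bg, anchor, side)
        draws = _sup_draws_null(bg, window, side, uniforms, null_level)
    else:
        raise ValueError("composition must be 'ecdf' or 'null'")
    return mc_quantile(draws, beta)


def test_kappa(sample, bg: BackgroundModel, window, side: str,
               beta: float = 0.05, M: int = 1000, seed=None,
               uniforms: np.ndarray | None = None,
               composition: str = "ecdf",
               null_level: float | None = None) -> TestResult:
    """Test the validity of the window's outer point as a search bound.

    ``side='left_tail'``: window ``(iota0, kappa0)``, null ``kappa0 <= a0``;
    ``side='right_tail'``: window ``(kappa0, lambda0)``, null ``kappa0 >= a0``.
    Accepted iff the observed sup statistic is below the simulated quantile.
    """
    ecdf = sample if isinstance(sample, EmpiricalCDF) else EmpiricalCDF(sample)
    stat = sup_abs_centered_ratio(ecdf, bg, window[0], window[1], side)
    q = simulate_test_quantile(ecdf, bg, window, side, M=M, beta=beta,
                               seed=seed, uniforms=uniforms,
                               composition=composition, null_level=null_level)
    return TestResult(statistic=stat, quantile=q, beta=beta,
                      M=M if uniforms is None else uniforms.shape[0],
                      accepted=stat <= q, window=(float(window[0]), float(window[1])),
                      side=side)


def _window_for(kappa: float, h0: float, problem: str):
    if problem == "right_support":
        return (kappa - h0, kappa), "left_tail"
    return (kappa, kappa + h0), "right_tail"


def search_kappa(sample, bg: BackgroundModel, grid, h0: float, problem: str,
                 beta: float = 0.05, M: int = 1000, seed=None) -> KappaEstimate:
    """Grid search for the boundary of the signal-free region.

    Every grid point is tested with the survival-side statistic over
    ``(kappa, kappa + h0)`` (``left_support``) or the CDF-side statistic over
    ``(kappa - h0, kappa)`` (``right_support``), against null-composed
    critical values whose ratio level is read off at the outermost grid point
    (the most signal-free region the grid offers).  The same ``M`` surrogate
    uniform samples are reused across grid points.

    Selection: for a left-supported signal the estimate is the smallest
    accepted grid point; for a right-supported signal the scan starts inside
    the valid region, so the estimate is the endpoint of the initial run of
    acceptances (the last accepted point before the first rejection).
    Windows that leave the interior of the background support are marked
    untestable and never accepted.
    """
    ecdf = sample if isinstance(sample, EmpiricalCDF) else EmpiricalCDF(sample)
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    rng = np.random.default_rng(seed)
    uniforms = np.sort(rng.random((M, ecdf.n)), axis=1)
    if problem == "right_support":
        side_all = "left_tail"
        level = null_ratio_level(ecdf, bg, float(grid[0]), side_all)
    elif problem == "left_support":
        side_all = "right_tail"
        level = null_ratio_level(ecdf, bg, float(grid[-1]), side_all)
    else:
        raise ValueError("problem must be 'right_support' or 'left_support'")
    results = []
    for kappa in grid:
        window, side = _window_for(kappa, h0, problem)
        lo, hi = window
        testable = ((side == "left_tail" and float(bg.cdf(lo)) > 0.0) or
                    (side == "right_tail" and float(bg.cdf(hi)) < 1.0))
        if not testable:
            results.append(TestResult(statistic=float("nan"), quantile=float("nan"),
                                      beta=beta, M=M, accepted=False,
                                      window=(float(lo), float(hi)), side=side,
                                      untestable=True))
            continue
        results.append(test_kappa(ecdf, bg, window, side, beta=beta,
                                  uniforms=uniforms, composition="null",
                                  null_level=level))
    acc = np.array([r.accepted for r in results])
    if problem == "left_support":
        if not acc.any():
            raise NoValidKappaError(results)
        kappa_hat = grid[np.argmax(acc)]        # smallest accepted
    else:
        if not acc[0]:
            raise NoValidKappaError(results)
        first_rej = np.argmin(acc) if not acc.all() else grid.size
        kappa_hat = grid[first_rej - 1]         # end of the initial accepted run
    return KappaEstimate(kappa_hat=float(kappa_hat), grid=grid, h0=float(h0),
                         per_kappa=results)
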