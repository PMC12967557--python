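"""Empirical CDF, background models, and the exact candidate-point engine.

The estimators in this package are defined through infima / suprema of ratios
of the empirical distribution function (a right-continuous step function) to a
continuous background CDF.  On every constancy piece of the ECDF such a ratio
is monotone in ``x`` (the numerator is frozen while the denominator moves), so
the extremum over an interval is attained at a finite set of candidate points:
interval endpoints, data points, and left limits at data points.  All
operations here evaluate those candidate sets exactly; no grids are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "EmpiricalCDF",
    "BackgroundModel",
    "background",
    "register_background",
    "inf_ratio_right",
    "inf_ratio_left",
    "sup_abs_centered_ratio",
    "DomainError",
]


class DomainError(ValueError):
    """Raised when an operation is requested outside its valid domain."""


# ---------------------------------------------------------------------------
# Empirical CDF
# ---------------------------------------------------------------------------

class EmpiricalCDF:
    """Right-continuous empirical distribution function of a 1-d sample.

    Ties are allowed; multiplicities are absorbed into jump sizes.  Evaluation
    is ``#{X_i <= x}/n``; ``left_limit`` gives ``#{X_i < x}/n``.
    """

    __slots__ = ("values", "n")

    def __init__(self, sample):
        values = np.asarray(sample, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("empirical CDF requires at least one observation")
        if not np.all(np.isfinite(values)):
            raise ValueError("sample contains non-finite values")
        self.values = np.sort(values)
        self.n = values.size

    def __call__(self, x):
        return np.searchsorted(self.values, x, side="right") / self.n

    def left_limit(self, x):
        return np.searchsorted(self.values, x, side="left") / self.n

    def unique_points(self):
        """Distinct data points with right-continuous and left-limit values."""
        pts = np.unique(self.values)
        f_plus = np.searchsorted(self.values, pts, side="right") / self.n
        f_minus = np.searchsorted(self.values, pts, side="left") / self.n
        return pts, f_plus, f_minus

    def __repr__(self):  # pragma: no cover
        return f"EmpiricalCDF(n={self.n})"


# ---------------------------------------------------------------------------
# Background models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundModel:
    """Known background component: continuous, strictly increasing CDF.

    Attributes
    ----------
    cdf, quantile : callables
        The distribution function and its inverse.
    support : tuple
        Interval ``[b1, b2]`` (possibly infinite) on which the CDF strictly
        increases.
    name : str
        Family tag used by the plug-in registry.
    """

    cdf: Callable
    quantile: Callable
    support: tuple = (-np.inf, np.inf)
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def survival(self, x):
        return 1.0 - np.asarray(self.cdf(x))

    @classmethod
    def from_frozen(cls, dist, name="scipy", params=None):
        lo, hi = dist.support()
        return cls(cdf=dist.cdf, quantile=dist.ppf, support=(float(lo), float(hi)),
                   name=name, params=params or {})


_REGISTRY = {}


def register_background(name, builder):
    """Register a background family: ``builder(**params) -> BackgroundModel``."""
    _REGISTRY[name] = builder


def background(family, **params):
    """Construct a background model from a family name and parameters."""
    try:
        builder = _REGISTRY[family]
    except KeyError:
        raise DomainError(f"unknown background family {family!r}; "
                          f"known: {sorted(_REGISTRY)}") from None
    return builder(**params)


register_background(
    "uniform",
    lambda a=0.0, b=1.0: BackgroundModel.from_frozen(
        stats.uniform(a, b - a), name="uniform", params={"a": a, "b": b}),
)
register_background(
    "gaussian",
    lambda mu=0.0, sigma=1.0: BackgroundModel.from_frozen(
        stats.norm(mu, sigma), name="gaussian", params={"mu": mu, "sigma": sigma}),
)
register_background("normal", lambda mu=0.0, sigma=1.0: background("gaussian", mu=mu, sigma=sigma))


# ---------------------------------------------------------------------------
# Candidate-point extrema
# ---------------------------------------------------------------------------

def inf_ratio_right(ecdf: EmpiricalCDF, bg: BackgroundModel, kappa0: float) -> float:
    """Exact ``inf_{x >= kappa0} F_n(x) / F_b(x)``.

    On each constancy piece of the ECDF the ratio decreases in ``x``, so piece
    infima sit at right-edge left limits; the tail limit as ``x -> sup supp``
    is 1.  Candidates: the value at ``kappa0``, left limits at data points
    beyond ``kappa0``, and 1.
    """
    fb_k = float(bg.cdf(kappa0))
    if fb_k <= 0.0:
        raise DomainError("F_b(kappa0) must be positive for the right-tail ratio")
    pts, _, f_minus = ecdf.unique_points()
    mask = pts > kappa0
    cands = [float(ecdf(kappa0)) / fb_k, 1.0]
    if np.any(mask):
        ratios = f_minus[mask] / np.asarray(bg.cdf(pts[mask]), dtype=float)
        cands.append(float(np.min(ratios)))
    return min(cands)


def inf_ratio_left(ecdf: EmpiricalCDF, bg: BackgroundModel, kappa0: float) -> float:
    """Exact ``inf_{x <= kappa0} (1 - F_n(x)) / (1 - F_b(x))``.

    Pieces are increasing in ``x`` so piece infima sit at left edges (data
    points); the left-tail limit is 1.
    """
    if float(bg.cdf(kappa0)) >= 1.0:
        raise DomainError("F_b(kappa0) must be below 1 for the left-tail ratio")
    pts, f_plus, _ = ecdf.unique_points()
    mask = pts <= kappa0
    cands = [1.0]
    if np.any(mask):
        ratios = (1.0 - f_plus[mask]) / (1.0 - np.asarray(bg.cdf(pts[mask]), dtype=float))
        cands.append(float(np.min(ratios)))
    return min(cands)


def _interval_candidates(ecdf: EmpiricalCDF, lo: float, hi: float):
    """Candidate evaluation points for extrema of ECDF-ratio processes on [lo, hi].

    Returns ``(x, f, is_left_limit)``: right-continuous values at ``lo``,
    interior data points and ``hi``, plus left-limit values at interior data
    points and ``hi``.  Any piecewise process with numerator a function of the
    ECDF value and continuous monotone denominator attains its extrema on this
    set.
    """
    pts = np.unique(ecdf.values)
    inner = pts[(pts > lo) & (pts < hi)]
    x_plus = np.concatenate(([lo], inner, [hi]))
    f_plus = ecdf(x_plus)
    x_minus = np.concatenate((inner, [hi]))
    f_minus = ecdf.left_limit(x_minus)
    x = np.concatenate((x_plus, x_minus))
    f = np.concatenate((f_plus, f_minus))
    flags = np.concatenate((np.zeros(x_plus.size, bool), np.ones(x_minus.size, bool)))
    return x, f, flags


def sup_abs_centered_ratio(ecdf: EmpiricalCDF, bg: BackgroundModel,
                           lo: float, hi: float, side: str) -> float:
    """Exact sup of ``sqrt(n) |R(x) - R(anchor)|`` over ``[lo, hi]``.

    ``side='left_tail'``: ``R = F_n/F_b`` anchored at ``hi`` (the one-sided
    test statistic for a lower search bound); ``side='right_tail'``:
    ``R = (1-F_n)/(1-F_b)`` anchored at ``lo`` (the survival-side statistic).
    """
    if not lo < hi:
        if lo == hi:
            return 0.0
        raise ValueError("window must satisfy lo <= hi")
    x, f, _ = _interval_candidates(ecdf, lo, hi)
    if side == "left_tail":
        den = np.asarray(bg.cdf(x), dtype=float)
        if float(bg.cdf(lo)) <= 0.0:
            raise DomainError("F_b(lo) must be positive for side='left_tail'")
        ratios = f / den
        anchor = float(ecdf(hi)) / float(bg.cdf(hi))
    elif side == "right_tail":
        den = 1.0 - np.asarray(bg.cdf(x), dtype=float)
        if float(bg.cdf(hi)) >= 1.0:
            raise DomainError("F_b(hi) must be below 1 for side='right_tail'")
        ratios = (1.0 - f) / den
        anchor = (1.0 - float(ecdf(lo))) / (1.0 - float(bg.cdf(lo)))
    else:
        raise ValueError("side must be 'left_tail' or 'right_tail'")
    return float(np.sqrt(ecdf.n) * np.max(np.abs(ratios - anchor)))
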