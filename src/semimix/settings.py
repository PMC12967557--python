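"""Synthetic two-component mixture scenarios with known ground truth.

Nine benchmark scenarios cover three shape constraints on the signal density
(monotone, convex-decreasing, log-concave) and both support orientations:

* ``1a-4``: uniform background on [0, 1], signal supported on ``[0, a0]``
  (the p-value orientation; ``problem='left_support'``),
* ``5-7``: standard Gaussian background, signal supported on ``[0, inf)``
  (``problem='right_support'``, with ``a0 = 0``).

Every scenario exposes exact CDF/density evaluators so estimators can be
validated without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .empirical import BackgroundModel, DomainError, background

__all__ = ["SettingSpec", "SettingTruth", "SETTINGS", "get_setting",
           "sample_setting", "setting_truth"]


@dataclass(frozen=True)
class SettingSpec:
    """One benchmark scenario: background + signal + mixing proportion."""

    id: str
    background: str            # family tag: "uniform" or "gaussian"
    signal: str                # human-readable signal tag
    constraint: str            # monotone | convex | logconcave
    problem: str               # left_support (signal on [0, a0]) | right_support
    alpha0: float
    a0: float

    def __post_init__(self):
        if not 0.0 < self.alpha0 < 1.0:
            raise DomainError("alpha0 must lie strictly inside (0, 1)")
        if self.problem not in ("left_support", "right_support"):
            raise DomainError(f"unknown problem orientation {self.problem!r}")


@dataclass(frozen=True)
class SettingTruth:
    """Exact evaluators for a scenario's mixture, background and signal."""

    F0: Callable
    Fb: Callable
    Fs: Callable
    fs: Callable
    f0: Callable


SETTINGS = {
    "1a": SettingSpec("1a", "uniform", "uniform(0,0.6)", "monotone", "left_support", 0.6, 0.6),
    "1b": SettingSpec("1b", "uniform", "uniform(0,0.6)", "monotone", "left_support", 0.8, 0.6),
    "2a": SettingSpec("2a", "uniform", "mix(beta(1,2)/2, uniform(0,0.5))", "monotone", "left_support", 0.6, 0.5),
    "2b": SettingSpec("2b", "uniform", "mix(beta(1,2)/2, uniform(0,0.5))", "monotone", "left_support", 0.8, 0.5),
    "3": SettingSpec("3", "uniform", "0.7*beta(1,2)", "convex", "left_support", 0.8, 0.7),
    "4": SettingSpec("4", "uniform", "0.6*beta(1,3)", "convex", "left_support", 0.8, 0.6),
    "5": SettingSpec("5", "gaussian", "gamma(2,1)", "logconcave", "right_support", 0.8, 0.0),
    "6": SettingSpec("6", "gaussian", "exp(1)", "logconcave", "right_support", 0.8, 0.0),
    "7": SettingSpec("7", "gaussian", "gamma(0.5,1)", "logconcave", "right_support", 0.8, 0.0),
}


def get_setting(setting_id) -> SettingSpec:
    try:
        return SETTINGS[str(setting_id)]
    except KeyError:
        raise DomainError(f"unknown setting id {setting_id!r}; "
                          f"known: {sorted(SETTINGS)}") from None


def background_model(spec: SettingSpec) -> BackgroundModel:
    return background(spec.background)


def _signal_sampler(spec: SettingSpec, rng: np.random.Generator):
    sid = spec.id
    if sid in ("1a", "1b"):
        return lambda k: rng.uniform(0.0, 0.6, size=k)
    if sid in ("2a", "2b"):
        # 50/50 mix of Beta(1,2)/2 and U(0, 1/2); density 3 - 4x on [0, 1/2]
        def draw(k):
            pick = rng.random(k) < 0.5
            out = np.empty(k)
            out[pick] = rng.beta(1.0, 2.0, size=int(pick.sum())) / 2.0
            out[~pick] = rng.uniform(0.0, 0.5, size=int((~pick).sum()))
            return out
        return draw
    if sid == "3":
        return lambda k: 0.7 * rng.beta(1.0, 2.0, size=k)
    if sid == "4":
        return lambda k: 0.6 * rng.beta(1.0, 3.0, size=k)
    if sid == "5":
        return lambda k: rng.gamma(2.0, 1.0, size=k)
    if sid == "6":
        return lambda k: rng.exponential(1.0, size=k)
    if sid == "7":
        return lambda k: rng.gamma(0.5, 1.0, size=k)
    raise DomainError(f"unknown setting id {sid!r}")


def sample_setting(spec, n: int, seed) -> np.ndarray:
    """Draw a sorted i.i.d. sample of size ``n`` from the scenario's mixture.

    Each observation comes from the signal with probability ``alpha0`` and from
    the background otherwise.  ``seed`` may be an int or a Generator.
    """
    if isinstance(spec, str):
        spec = get_setting(spec)
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    from_signal = rng.random(n) < spec.alpha0
    k = int(from_signal.sum())
    out = np.empty(n)
    if spec.background == "uniform":
        out[~from_signal] = rng.uniform(0.0, 1.0, size=n - k)
    else:
        out[~from_signal] = rng.standard_normal(n - k)
    out[from_signal] = _signal_sampler(spec, rng)(k)
    return np.sort(out)


def _signal_truth(spec: SettingSpec):
    sid = spec.id
    if sid in ("1a", "1b"):
        dist = stats.uniform(0.0, 0.6)
        return dist.cdf, dist.pdf
    if sid in ("2a", "2b"):
        def Fs(x):
            x = np.asarray(x, dtype=float)
            return np.clip(3.0 * x - 2.0 * x ** 2, 0.0, None) * (x > 0) * (x < 0.5) + (x >= 0.5)
        def fs(x):
            x = np.asarray(x, dtype=float)
            return np.where((x >= 0.0) & (x <= 0.5), 3.0 - 4.0 * x, 0.0)
        return Fs, fs
    if sid in ("3", "4"):
        scale = 0.7 if sid == "3" else 0.6
        b = 2.0 if sid == "3" else 3.0
        dist = stats.beta(1.0, b, scale=scale)
        return dist.cdf, dist.pdf
    if sid == "5":
        dist = stats.gamma(2.0)
    elif sid == "6":
        dist = stats.expon()
    elif sid == "7":
        dist = stats.gamma(0.5)
    else:
        raise DomainError(f"unknown setting id {sid!r}")
    return dist.cdf, dist.pdf


def setting_truth(spec) -> SettingTruth:
    """Exact mixture/background/signal evaluators for a scenario."""
    if isinstance(spec, str):
        spec = get_setting(spec)
    bg = background_model(spec)
    Fs, fs = _signal_truth(spec)
    a = spec.alpha0
    if spec.background == "uniform":
        fb = stats.uniform(0.0, 1.0).pdf
    else:
        fb = stats.norm().pdf

    def F0(x):
        return (1.0 - a) * np.asarray(bg.cdf(x)) + a * np.asarray(Fs(x))

    def f0(x):
        return (1.0 - a) * np.asarray(fb(x)) + a * np.asarray(fs(x))

    return SettingTruth(F0=F0, Fb=bg.cdf, Fs=Fs, fs=fs, f0=f0)
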