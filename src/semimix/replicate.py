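"""Replication experiments and the generic p-value workflow.

Drives the benchmark scenarios end to end: per-scenario acceptance rates and
endpoint-estimate summaries, grid-search hit probabilities, mixing-proportion
comparisons against the distance-based comparator, and the comparison of the
scaled estimation error with the simulated limit law.  Every table cell is a
pure function of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .empirical import BackgroundModel, EmpiricalCDF, background
from .estimate import (default_bn, estimate_a0, estimate_alpha,
                       simulate_alpha_limit)
from .kappa import NoValidKappaError, search_kappa, test_kappa
from .monotone import grenander_fit, sample_from_fit, signal_density
from .patra_sen import default_cn, ps_estimate
from .settings import SETTINGS, get_setting, sample_setting, setting_truth

__all__ = ["ExperimentConfig", "DEFAULT_WINDOWS", "DEFAULT_GRIDS",
           "setting_background", "setting_kappa0", "endpoint_experiment",
           "kappa_search_experiment", "alpha_comparison_experiment",
           "compare_error_to_limit", "pvalue_workflow", "run_table_experiment"]

#: Test windows per scenario: (kappa0, lambda0) for left-supported signals,
#: (iota0, kappa0) for right-supported ones.
DEFAULT_WINDOWS = {
    "1a": (0.8, 0.9), "1b": (0.8, 0.9),
    "2a": (0.6, 0.7), "2b": (0.6, 0.7),
    "3": (0.8, 0.9), "4": (0.7, 0.8),
    "5": (-1.5, -1.0), "6": (-1.5, -1.0), "7": (-1.5, -1.0),
}

DEFAULT_GRIDS = {
    **{k: (np.round(np.arange(0.2, 0.801, 0.05), 10), 0.05)
       for k in ("1a", "1b", "2a", "2b", "3", "4")},
    **{k: (np.round(np.arange(-1.0, 1.001, 0.1), 10), 0.1)
       for k in ("5", "6", "7")},
}


def setting_background(spec) -> BackgroundModel:
    if isinstance(spec, str):
        spec = get_setting(spec)
    return background(spec.background)


def setting_kappa0(setting_id: str) -> float:
    """The scenario's default search bound: the window endpoint nearest a0."""
    w = DEFAULT_WINDOWS[str(setting_id)]
    spec = get_setting(setting_id)
    return w[0] if spec.problem == "left_support" else w[1]


@dataclass
class ExperimentConfig:
    setting_ids: tuple = tuple(SETTINGS)
    n_values: tuple = (1000,)
    replications: int = 100
    seed: int = 0
    M: int = 1000
    beta: float = 0.05


def _window_side(spec):
    return "right_tail" if spec.problem == "left_support" else "left_tail"


def endpoint_experiment(setting_id, n, reps, seed, M=1000, beta=0.05,
                        subsample=True):
    """Acceptance rate of the default search bound and summary of a_hat.

    Replicates that pass the validity test contribute an endpoint estimate;
    when ``subsample`` is set, a random 90% of the passing estimates is
    retained before summarising (900 out of 1000 at the full scale).
    """
    spec = get_setting(setting_id)
    bg = setting_background(spec)
    window = DEFAULT_WINDOWS[str(setting_id)]
    kappa0 = setting_kappa0(setting_id)
    side = _window_side(spec)
    rng = np.random.default_rng(seed)
    a_hats, accepted = [], 0
    for _ in range(reps):
        s = sample_setting(spec, n, rng)
        ecdf = EmpiricalCDF(s)
        res = test_kappa(ecdf, bg, window, side, beta=beta, M=M, seed=rng)
        if res.accepted:
            accepted += 1
            alpha = estimate_alpha(ecdf, bg, kappa0, spec.problem)
            a_hats.append(estimate_a0(ecdf, bg, kappa0, alpha).a_hat)
    a_hats = np.asarray(a_hats)
    if subsample and a_hats.size:
        keep = max(1, int(round(0.9 * a_hats.size)))
        a_hats = rng.choice(a_hats, size=keep, replace=False)
    return {
        "setting": str(setting_id), "n": n, "reps": reps,
        "acceptance_rate": accepted / reps,
        "a_mean": float(np.mean(a_hats)) if a_hats.size else float("nan"),
        "a_median": float(np.median(a_hats)) if a_hats.size else float("nan"),
        "a_sd": float(np.std(a_hats, ddof=1)) if a_hats.size > 1 else float("nan"),
        "kept": int(a_hats.size),
    }


def kappa_search_experiment(setting_id, n, reps, seed, M=1000, beta=0.05):
    """Hit probability and summary of the grid-searched search bound."""
    spec = get_setting(setting_id)
    bg = setting_background(spec)
    grid, h0 = DEFAULT_GRIDS[str(setting_id)]
    rng = np.random.default_rng(seed)
    hats = []
    failures = 0
    for _ in range(reps):
        s = sample_setting(spec, n, rng)
        try:
            hats.append(search_kappa(s, bg, grid, h0, spec.problem,
                                     beta=beta, M=M, seed=rng).kappa_hat)
        except NoValidKappaError:
            failures += 1
    hats = np.asarray(hats)
    if spec.problem == "left_support":
        lo, hi = spec.a0, spec.a0 + h0
    else:
        lo, hi = spec.a0 - h0, spec.a0
    eps = 1e-9
    return {
        "setting": str(setting_id), "n": n, "reps": reps,
        "hit_prob": float(np.mean((hats >= lo - eps) & (hats <= hi + eps)))
                    if hats.size else float("nan"),
        "kappa_mean": float(np.mean(hats)) if hats.size else float("nan"),
        "kappa_sd": float(np.std(hats, ddof=1)) if hats.size > 1 else float("nan"),
        "failures": failures,
    }


def alpha_comparison_experiment(setting_id, n, reps, seed, kappa0=None,
                                include_comparator=True):
    """Mean and RMSE of the ratio estimator and the distance-based comparator."""
    spec = get_setting(setting_id)
    bg = setting_background(spec)
    if kappa0 is None:
        kappa0 = setting_kappa0(setting_id)
    rng = np.random.default_rng(seed)
    ours, theirs = [], []
    for _ in range(reps):
        s = sample_setting(spec, n, rng)
        ecdf = EmpiricalCDF(s)
        ours.append(estimate_alpha(ecdf, bg, kappa0, spec.problem).alpha_hat)
        if include_comparator:
            theirs.append(ps_estimate(ecdf, bg, c_n=default_cn(n)).alpha)
    ours = np.asarray(ours)
    out = {
        "setting": str(setting_id), "n": n, "reps": reps, "kappa0": kappa0,
        "alpha_mean": float(np.mean(ours)),
        "alpha_rmse": float(np.sqrt(np.mean((ours - spec.alpha0) ** 2))),
    }
    if include_comparator:
        theirs = np.asarray(theirs)
        out["ps_mean"] = float(np.mean(theirs))
        out["ps_rmse"] = float(np.sqrt(np.mean((theirs - spec.alpha0) ** 2)))
    return out


def compare_error_to_limit(setting_id, n, reps, N=None, M=5000, seed=0):
    """KS distance between sqrt(n)(alpha_hat - alpha0) and the simulated limit.

    Uses the scenario's exact mixture CDF (oracle mode) over the signal-free
    window between the default search bound and the true endpoint.
    """
    spec = get_setting(setting_id)
    bg = setting_background(spec)
    truth = setting_truth(spec)
    kappa0 = setting_kappa0(setting_id)
    if N is None:
        N = n
    rng = np.random.default_rng(seed)
    errs = np.empty(reps)
    for r in range(reps):
        s = sample_setting(spec, n, rng)
        a = estimate_alpha(s, bg, kappa0, spec.problem)
        errs[r] = math.sqrt(n) * (a.alpha_hat - spec.alpha0)
    interval = ((kappa0, spec.a0) if spec.problem == "right_support"
                else (spec.a0, kappa0))
    limit = simulate_alpha_limit(truth.F0, bg, interval, spec.problem,
                                 N=N, M=M, seed=rng)
    from scipy.stats import ks_2samp
    ks = float(ks_2samp(errs, limit.draws).statistic)
    return {"setting": str(setting_id), "n": n, "reps": reps, "ks": ks,
            "errors": errs, "limit_draws": limit.draws}


def pvalue_workflow(pvalues, grid=None, h0=0.01, beta=0.05, M=1000,
                    resamples=None, level=0.95, seed=0):
    """Full analysis of a p-value sample under the uniform null.

    Searches the grid for a valid search bound, estimates the signal
    proportion and the support endpoint of the alternative's p-value
    distribution, and fits the monotone signal density.  Optional
    ``resamples`` (an iterable of p-value vectors, e.g. from subject
    resampling) yield a symmetric CI for the proportion, re-using the
    searched bound.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value sample")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    bg = background("uniform")
    if grid is None:
        grid = np.round(np.arange(0.01, 0.301, h0), 10)
    est = search_kappa(p, bg, grid, h0, "left_support", beta=beta, M=M,
                       seed=seed)
    kappa_hat = est.kappa_hat
    ecdf = EmpiricalCDF(p)
    alpha = estimate_alpha(ecdf, bg, kappa_hat, "left_support")
    a0_est = estimate_a0(ecdf, bg, kappa_hat, alpha)
    alpha_c = min(max(alpha.alpha_hat, 1e-12), 1.0)
    f_s = signal_density(grenander_fit(ecdf), alpha_c)
    out = {"kappa_hat": kappa_hat, "alpha_hat": alpha.alpha_hat,
           "a_hat": a0_est.a_hat, "f_hat_s": f_s, "search": est}
    if resamples is not None:
        boots = np.array([
            estimate_alpha(np.asarray(pv, dtype=float), bg, kappa_hat,
                           "left_support").alpha_hat
            for pv in resamples])
        lo = float(np.quantile(boots, (1 - level) / 2))
        hi = float(np.quantile(boots, (1 + level) / 2))
        out["resample_stats"] = {"mean": float(boots.mean()),
                                 "median": float(np.median(boots)),
                                 "sd": float(boots.std(ddof=1)),
                                 "ci": (lo, hi)}
    return out


def run_table_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Tidy table of per-scenario metrics at the configured scale."""
    rows = []
    rng = np.random.default_rng(config.seed)
    for sid in config.setting_ids:
        for n in config.n_values:
            sub = int(rng.integers(2 ** 31))
            row = endpoint_experiment(sid, n, config.replications, sub,
                                      M=config.M, beta=config.beta)
            row.update({k: v for k, v in alpha_comparison_experiment(
                sid, n, config.replications, sub).items()
                if k not in row})
            rows.append(row)
    return pd.DataFrame(rows)
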