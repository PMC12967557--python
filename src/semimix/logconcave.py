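"""Log-concave signal estimation under a Gaussian background via pseudo-EM.

The signal density is modelled as ``exp(psi)`` with ``psi`` concave; the
maximum-likelihood ``psi`` is piecewise linear with kinks at (a subset of)
the observations.  The weighted MLE maximises

    L(psi) = sum_i w_i psi(X_i) - int exp(psi)

over concave ``psi`` on ``[X_(1), X_(n)]``.  Concave piecewise-linear
functions are parametrised as ``psi(x) = a + b (x - z_1) - sum_k beta_k
(x - z_k)_+`` with ``beta_k >= 0`` over hinge locations at the interior data
points, which turns the problem into a smooth concave programme with simple
sign constraints.  A support-reduction scheme keeps a small active set of
hinges: Newton steps on the active coordinates (with exact segment-wise
integrals of ``exp(linear)``), adding the most violated hinge direction and
dropping hinges driven to zero.  At the optimum ``int exp(psi) = 1``
automatically (the constant direction is unconstrained).

The mixture version alternates this weighted MLE (M-step) with
responsibilities for the known Gaussian background (E-step), holding the
externally estimated mixing proportion fixed — a pseudo-EM in which only the
signal density is updated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .empirical import DomainError

__all__ = ["LogConcaveFit", "PseudoEMResult", "weighted_logconcave_mle",
           "pseudo_logconcave_em", "DegenerateWeightsError"]


class DegenerateWeightsError(RuntimeError):
    """All responsibility assigned to the background; no signal to fit."""


# ---------------------------------------------------------------------------
# Stable integrals of exp(linear) times polynomials
# ---------------------------------------------------------------------------

def _phi012(y: np.ndarray):
    """phi_k(y) = int_0^1 t^k e^{y t} dt, computed stably near y = 0."""
    y = np.asarray(y, dtype=float)
    small = np.abs(y) < 1e-5
    ys = np.where(small, 0.0, y)
    ey = np.exp(ys)
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(small, 1.0 + y / 2.0 + y * y / 6.0, (ey - 1.0) / ys)
        p1 = np.where(small, 0.5 + y / 3.0 + y * y / 8.0,
                      (ey * (ys - 1.0) + 1.0) / ys ** 2)
        p2 = np.where(small, 1.0 / 3.0 + y / 4.0 + y * y / 10.0,
                      (ey * (ys * ys - 2.0 * ys + 2.0) - 2.0) / ys ** 3)
    return p0, p1, p2


def _segment_moments(p, q, psi_p, psi_q):
    """(S0, S1, S2) = int_p^q x^k e^{psi} dx for linear psi on [p, q].

    Factored from the larger endpoint so the exponentials never overflow for
    finite psi values.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    psi_p = np.asarray(psi_p, dtype=float)
    psi_q = np.asarray(psi_q, dtype=float)
    d = q - p
    y = psi_q - psi_p
    ym = -np.abs(y)
    p0, p1, p2 = _phi012(ym)
    up = y <= 0.0
    e = np.exp(np.maximum(psi_p, psi_q))
    f0 = p0
    f1 = np.where(up, p1, p0 - p1)
    f2 = np.where(up, p2, p0 - 2.0 * p1 + p2)
    i0 = e * d * f0                 # int e^psi
    i1 = e * d * d * f1             # int (x-p) e^psi
    i2 = e * d ** 3 * f2            # int (x-p)^2 e^psi
    return i0, p * i0 + i1, p * p * i0 + 2.0 * p * i1 + i2


# ---------------------------------------------------------------------------
# The fitted object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogConcaveFit:
    """Concave piecewise-linear log-density on [knots[0], knots[-1]]."""

    knots: np.ndarray           # breakpoints (slope-change points incl. ends)
    psi: np.ndarray             # log-density values at the breakpoints
    objective: float            # weighted criterion value at the fit
    gap: float                  # largest violated hinge direction at exit
    n: int
    shape: str = "logconcave"

    @property
    def support(self) -> tuple:
        return (float(self.knots[0]), float(self.knots[-1]))

    def log_density(self, x):
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.knots, self.psi)
        return np.where((x >= self.knots[0]) & (x <= self.knots[-1]), out, -np.inf)

    def __call__(self, x):
        with np.errstate(over="ignore"):
            return np.exp(self.log_density(x))

    @property
    def normalization(self) -> float:
        i0, _, _ = _segment_moments(self.knots[:-1], self.knots[1:],
                                    self.psi[:-1], self.psi[1:])
        return float(np.sum(i0))


# ---------------------------------------------------------------------------
# Weighted MLE solver
# ---------------------------------------------------------------------------

class _Workspace:
    """Hinge-parametrised concave programme for one (points, weights) pair."""

    def __init__(self, z: np.ndarray, w: np.ndarray):
        self.z = z
        self.w = w
        self.z1 = z[0]
        self.zm = z[-1]
        # data-term coefficients: suffix sums for  sum_i w_i (z_i - t)_+
        self.cw = np.cumsum(w[::-1])[::-1]            # sum of w_i for z_i >= z_k
        self.cwz = np.cumsum((w * z)[::-1])[::-1]     # sum of w_i z_i for z_i >= z_k
        self.g_a = float(np.sum(w))
        self.g_b = float(np.sum(w * (z - self.z1)))

    def hinge_data_term(self, t_idx):
        """sum_i w_i (z_i - z_k)_+ for candidate indices (exact: z sorted)."""
        k = np.asarray(t_idx, dtype=int)
        return self.cwz[k] - self.z[k] * self.cw[k]

    def psi_at(self, theta, act_idx, x):
        a, b = theta[0], theta[1]
        val = a + b * (np.asarray(x) - self.z1)
        for j, k in enumerate(act_idx):
            val = val - theta[2 + j] * np.clip(np.asarray(x) - self.z[k], 0.0, None)
        return val

    def objective(self, theta, act_idx):
        data = (theta[0] * self.g_a + theta[1] * self.g_b
                - float(np.dot(theta[2:], self.hinge_data_term(act_idx))))
        bp = np.concatenate(([self.z1], self.z[act_idx], [self.zm]))
        psi_bp = self.psi_at(theta, act_idx, bp)
        i0, _, _ = _segment_moments(bp[:-1], bp[1:], psi_bp[:-1], psi_bp[1:])
        return data - float(np.sum(i0))

    def grad_hess(self, theta, act_idx):
        """Gradient and Hessian of the objective on the active coordinates."""
        bp = np.concatenate(([self.z1], self.z[act_idx], [self.zm]))
        psi_bp = self.psi_at(theta, act_idx, bp)
        s0, s1, s2 = _segment_moments(bp[:-1], bp[1:], psi_bp[:-1], psi_bp[1:])
        d = 2 + len(act_idx)
        # basis on segment s: v_j(x) = P[j] + Q[j] x  (hinge j active iff seg >= j+1)
        grad = np.empty(d)
        hess = np.zeros((d, d))
        nseg = bp.size - 1
        P = np.zeros((d, nseg))
        Q = np.zeros((d, nseg))
        P[0, :] = 1.0
        P[1, :] = -self.z1
        Q[1, :] = 1.0
        for j, k in enumerate(act_idx):
            P[2 + j, j + 1:] = self.z[k]
            Q[2 + j, j + 1:] = -1.0
        int_v = P @ s0 + Q @ s1
        g_data = np.concatenate(([self.g_a, self.g_b],
                                 -self.hinge_data_term(act_idx)))
        grad[:] = g_data - int_v
        hess -= (P * s0) @ P.T + (P * s1) @ Q.T + (Q * s1) @ P.T + (Q * s2) @ Q.T
        return grad, hess

    def screen(self, theta, act_idx):
        """Directional derivatives toward every interior hinge candidate."""
        z = self.z
        bp = np.concatenate(([self.z1], z[act_idx], [self.zm]))
        psi_bp = self.psi_at(theta, act_idx, bp)
        s0, s1, _ = _segment_moments(bp[:-1], bp[1:], psi_bp[:-1], psi_bp[1:])
        # tail integrals T0(t) = int_t^zm e^psi, T1(t) = int_t^zm x e^psi
        tail0 = np.concatenate((np.cumsum(s0[::-1])[::-1], [0.0]))
        tail1 = np.concatenate((np.cumsum(s1[::-1])[::-1], [0.0]))
        cand = np.arange(1, z.size - 1)
        seg = np.searchsorted(bp, z[cand], side="right") - 1
        seg = np.clip(seg, 0, bp.size - 2)
        # partial integral from the candidate to its segment's right end
        q_ = bp[seg + 1]
        psi_c = self.psi_at(theta, act_idx, z[cand])
        psi_q = psi_bp[seg + 1]
        i0p, i1p, _ = _segment_moments(z[cand], q_, psi_c, psi_q)
        int_hinge = (tail1[seg + 1] + i1p) - z[cand] * (tail0[seg + 1] + i0p)
        # derivative toward increasing beta_k: -(data term) + integral term
        return -self.hinge_data_term(cand) + int_hinge, cand


def weighted_logconcave_mle(points, weights=None, tol: float = 1e-7,
                            max_outer: int = 200, inner_tol: float = 1e-9,
                            max_newton: int = 60,
                            init: "LogConcaveFit | None" = None) -> LogConcaveFit:
    """Weighted log-concave maximum-likelihood density estimate.

    Maximises ``sum w_i psi(X_i) - int exp(psi)`` over concave ``psi`` on the
    range of the points.  ``weights`` default to uniform; they must be
    non-negative and are normalised to sum to one.  The optimality gap
    reported is the largest directional derivative toward an unused hinge;
    the outer loop also stops on objective stagnation (a direction whose
    predicted gain is below numerical resolution).  ``init`` warm-starts from
    a previous fit on the same points (used by the EM driver).
    """
    z = np.asarray(points, dtype=float).ravel()
    order = np.argsort(z)
    z = z[order]
    if weights is None:
        w = np.full(z.size, 1.0 / z.size)
    else:
        w = np.asarray(weights, dtype=float).ravel()[order]
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        s = w.sum()
        if s <= 0:
            raise DegenerateWeightsError("weights sum to zero")
        w = w / s
    # merge duplicate points
    zu, inv = np.unique(z, return_inverse=True)
    if zu.size < 2:
        raise DomainError("need at least 2 distinct points")
    wu = np.zeros(zu.size)
    np.add.at(wu, inv, w)
    ws = _Workspace(zu, wu)

    theta = np.array([math.log(1.0 / (zu[-1] - zu[0])), 0.0])
    act: list[int] = []
    if init is not None and init.knots[0] == zu[0] and init.knots[-1] == zu[-1]:
        slopes = np.diff(init.psi) / np.diff(init.knots)
        hinge_idx = np.searchsorted(zu, init.knots[1:-1])
        hinge_idx = hinge_idx[(hinge_idx > 0) & (hinge_idx < zu.size - 1)]
        act = sorted(set(int(i) for i in hinge_idx))
        beta = np.maximum(-np.diff(slopes), 0.0)
        if beta.size == len(act):
            theta = np.concatenate(([init.psi[0], slopes[0]], beta))
    gap = np.inf
    prev_obj = -np.inf
    stall = 0
    for outer in range(max_outer):
        theta = _newton(ws, theta, act, inner_tol, max_newton)
        # prune zero hinges
        keep = [j for j in range(len(act)) if theta[2 + j] > 0.0]
        act = [act[j] for j in keep]
        theta = np.concatenate((theta[:2], theta[2:][keep]))
        derivs, cand = ws.screen(theta, act)
        free = np.array([c not in act for c in cand])
        gap = float(np.max(derivs[free])) if free.any() else 0.0
        if gap <= tol:
            break
        obj = ws.objective(theta, act)
        stall = stall + 1 if obj - prev_obj <= 1e-11 * max(1.0, abs(obj)) else 0
        prev_obj = obj
        if stall >= 2:
            break
        k = int(cand[free][int(np.argmax(derivs[free]))])
        pos = int(np.searchsorted([ws.z[a] for a in act], ws.z[k]))
        act.insert(pos, k)
        theta = np.insert(theta, 2 + pos, 0.0)
    bp = np.concatenate(([zu[0]], zu[act], [zu[-1]]))
    psi_bp = np.asarray(ws.psi_at(theta, act, bp), dtype=float)
    # exact normalisation: shifting psi by -log(int e^psi) is the optimal move
    # along the constant direction, so it never decreases the objective
    i0, _, _ = _segment_moments(bp[:-1], bp[1:], psi_bp[:-1], psi_bp[1:])
    log_norm = math.log(float(np.sum(i0)))
    psi_bp = psi_bp - log_norm
    data_term = float(np.dot(wu, np.interp(zu, bp, psi_bp)))
    return LogConcaveFit(knots=bp, psi=psi_bp, gap=gap,
                         objective=data_term - 1.0, n=z.size)


def _newton(ws: _Workspace, theta: np.ndarray, act: list, tol: float,
            max_iter: int) -> np.ndarray:
    """Damped Newton on the active coordinates, keeping beta >= 0."""
    obj = ws.objective(theta, act)
    for _ in range(max_iter):
        grad, hess = ws.grad_hess(theta, act)
        scale = max(1.0, float(np.max(np.abs(theta))))
        if np.max(np.abs(grad)) < tol * max(1.0, abs(obj)) * scale:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = grad
        # largest feasible step keeping beta >= 0
        t_max = 1.0
        for j in range(len(act)):
            sj = step[2 + j]
            if sj < 0.0:
                t_max = min(t_max, -theta[2 + j] / sj)
        t = t_max
        improved = False
        for _bs in range(50):
            cand = theta + t * step
            cand[2:] = np.maximum(cand[2:], 0.0)
            val = ws.objective(cand, act)
            if np.isfinite(val) and val >= obj - 1e-14:
                if val > obj or t < 1e-12:
                    theta, obj, improved = cand, val, True
                    break
            t *= 0.5
        if not improved:
            break
    return theta


# ---------------------------------------------------------------------------
# Pseudo-EM for the Gaussian-background mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudoEMResult:
    fit: LogConcaveFit          # fitted signal log-density
    gamma: np.ndarray           # final background responsibilities
    alpha_hat: float
    iterations: int
    converged: bool
    trace: np.ndarray = field(repr=False)      # per-iteration max |d gamma|
    loglik_trace: np.ndarray = field(repr=False)

    def signal_density(self, x):
        return self.fit(x)


def pseudo_logconcave_em(sample, alpha_hat, k_max: int = 250,
                         tol: float = 5e-6, bg=None) -> PseudoEMResult:
    """EM for the signal density in a Gaussian-background mixture.

    The mixing proportion is held fixed at ``alpha_hat`` (estimated
    externally at the parametric rate).  E-step: background responsibilities
    ``gamma_i = (1-a) phi(X_i) / ((1-a) phi(X_i) + a g(X_i))``; M-step:
    weighted log-concave MLE with ``w_i = (1 - gamma_i)/(n - sum gamma)``.
    Stops when ``max_i |gamma_i^(k+1) - gamma_i^(k)| < tol``.  The signal
    estimate is initialised as the Gaussian with the sample's moments.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise DomainError("need at least 2 observations")
    if hasattr(alpha_hat, "alpha_hat"):
        alpha_hat = alpha_hat.alpha_hat
    if not 0.0 < alpha_hat <= 1.0:
        raise DomainError("alpha_hat must lie in (0, 1]")
    phi_x = stats.norm.pdf(x)  # background fixed to the standard normal

    if alpha_hat >= 1.0:
        fit = weighted_logconcave_mle(x)
        gamma = np.zeros(n)
        ll = float(np.mean(np.log(np.maximum(fit(x), 1e-300))))
        return PseudoEMResult(fit=fit, gamma=gamma, alpha_hat=1.0, iterations=1,
                              converged=True, trace=np.array([0.0]),
                              loglik_trace=np.array([ll]))

    mu, sd = float(np.mean(x)), float(np.std(x))
    g_x = stats.norm.pdf(x, loc=mu, scale=max(sd, 1e-12))
    gamma = None
    fit = None
    trace, lls = [], []
    converged = False
    it = 0
    for it in range(1, k_max + 1):
        denom = (1.0 - alpha_hat) * phi_x + alpha_hat * g_x
        new_gamma = np.where(denom > 0.0, (1.0 - alpha_hat) * phi_x / denom, 1.0)
        delta = float(np.max(np.abs(new_gamma - gamma))) if gamma is not None else np.inf
        gamma = new_gamma
        tot = n - float(np.sum(gamma))
        if tot <= 0.0:
            raise DegenerateWeightsError("all mass assigned to the background")
        w = (1.0 - gamma) / tot
        fit = weighted_logconcave_mle(x, w, init=fit)
        g_x = fit(x)
        lls.append(float(np.mean(np.log(np.maximum(
            (1.0 - alpha_hat) * phi_x + alpha_hat * g_x, 1e-300)))))
        if np.isfinite(delta):
            trace.append(delta)
            if delta < tol:
                converged = True
                break
    return PseudoEMResult(fit=fit, gamma=gamma, alpha_hat=float(alpha_hat),
                          iterations=it, converged=converged,
                          trace=np.asarray(trace), loglik_trace=np.asarray(lls))
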