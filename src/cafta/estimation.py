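"""Local maximum-likelihood fitting and the sequential collaborative update.

The collaborative estimator visits the K sites in a fixed order.  Site 1
solves its local score equation; site k >= 2 solves the renewable
estimating equation

    U_k(theta) + [sum_{j<k} H_j(theta_hat_j)] (theta_hat_{k-1} - theta) = 0,

where H_j is the sensitivity (observed information) matrix reported by
site j at its own update.  Only the running estimate and the cumulative
sensitivity/variability matrices cross site boundaries — never
subject-level data.  At the end, the model-based covariance is
(sum_j H_j)^-1 and the robust alternative is the sandwich
(sum H)^-1 (sum V) (sum H)^-T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize

from .aft_core import (
    ErrorFamily,
    SiteData,
    Theta,
    loglik,
    score,
    sensitivity,
    variability,
)

__all__ = [
    "SiteSummary",
    "CaftaState",
    "FitResult",
    "ConvergenceError",
    "fit_local",
    "renew",
    "run_cafta",
    "sandwich_cov",
    "order_by_events",
]

logger = logging.getLogger(__name__)

# Newton-Raphson controls
_TOL = 1e-8          # max-abs estimating-function value at convergence
# The gg shape direction is differentiated numerically and its equation
# is solvable only to the accuracy of that derivative (special-function
# roughness at extreme shapes).  5e-3 bounds the implied log-likelihood
# slack below ~1e-4 on the flat shape ridge.
_TOL_Q = 5e-3
_MAX_ITER = 100
_MAX_HALVING = 30
_RIDGE = 1e-8        # scaled by trace/dim on near-singular Hessians


def _within_tol(g: "np.ndarray", has_q: bool, scale: float = 1.0) -> bool:
    # backstop for degenerate scales (e.g. sigma -> 0 inflates the score
    # units): an estimating-function residual below 1e-12 x the largest
    # curvature entry corresponds to a parameter resolution of 1e-12
    tol = max(_TOL, 1e-12 * scale)
    if not has_q:
        return bool(np.max(np.abs(g)) < tol)
    return bool(np.max(np.abs(g[:-1])) < tol and abs(g[-1]) < _TOL_Q)


class ConvergenceError(RuntimeError):
    """Raised when a fit that must succeed (e.g. the first site) fails."""


@dataclass
class SiteSummary:
    """The only message a site ever shares: its estimate and the
    sensitivity/variability matrices evaluated there, plus the sample
    size and optionally a plug-in log-likelihood value."""

    theta_hat: Theta
    H: np.ndarray
    V: np.ndarray
    n: int
    loglik_at: tuple[np.ndarray, float] | None = None

    def __post_init__(self) -> None:
        d = self.theta_hat.dim
        if self.H.shape != (d, d) or self.V.shape != (d, d):
            raise ValueError("summary matrices must match the parameter dimension")


@dataclass
class CaftaState:
    """Running collaborative state after absorbing k sites."""

    theta_hat: Theta
    H_cum: np.ndarray
    V_cum: np.ndarray
    N_cum: int
    k: int
    converged: bool = True
    n_iter_last: int = 0

    @classmethod
    def from_summary(cls, summary: SiteSummary, converged: bool = True,
                     n_iter: int = 0) -> "CaftaState":
        return cls(theta_hat=summary.theta_hat, H_cum=summary.H.copy(),
                   V_cum=summary.V.copy(), N_cum=summary.n, k=1,
                   converged=converged, n_iter_last=n_iter)


@dataclass
class FitResult:
    """Final collaborative fit with both covariance estimates."""

    theta_hat: Theta
    cov_model: np.ndarray
    cov_sandwich: np.ndarray
    se_model: np.ndarray
    se_sandwich: np.ndarray
    z_scores: np.ndarray
    loglik: float
    aic: float
    n_total: int
    converged: bool
    n_iter: int
    n_sites: int = 0
    failed_sites: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Newton-Raphson with step halving on the (penalized) score equation
# ---------------------------------------------------------------------------


def _solve_equation(family: ErrorFamily, data: SiteData, init: np.ndarray,
                    H_prev: np.ndarray | None = None,
                    theta_prev: np.ndarray | None = None):
    """Root-find G(theta) = U(theta) + H_prev (theta_prev - theta) = 0.

    G is the gradient of the penalized log-likelihood
    phi(theta) = l(theta) - (theta - theta_prev)' H_prev (theta - theta_prev)/2
    (the plain likelihood when H_prev = 0).  Newton steps are taken on
    the internal parameterization (alpha, beta, log sigma [, q]), with
    the transformed Hessian forced positive definite by an adaptive
    ridge and an Armijo backtracking line search on phi, so every step
    is an ascent step and sigma stays positive by construction.
    Convergence is declared on the natural-scale estimating function:
    max-abs value below 1e-8.  Returns (theta_vec, converged, n_iter).
    """
    p = data.p
    has_q = family.free_q
    sig_idx = p + 1
    dim = init.shape[0]
    if H_prev is None:
        H_prev = np.zeros((dim, dim))
        theta_prev = init

    def _theta(vec: np.ndarray) -> Theta:
        return Theta.from_array(vec, p, has_q=has_q)

    def G(vec: np.ndarray) -> np.ndarray:
        return score(family, _theta(vec), data) + H_prev @ (theta_prev - vec)

    def phi(vec: np.ndarray) -> float:
        d = vec - theta_prev
        return loglik(family, _theta(vec), data) - 0.5 * d @ H_prev @ d

    th, ok, it = _ascent_newton(G, phi, family, data, init, H_prev, sig_idx, has_q, p)
    if ok:
        return th, True, it
    # quasi-Newton fallback on the same objective, then one more polish
    th2 = _fallback_optimize(family, data, th if np.all(np.isfinite(th)) else init,
                             H_prev, theta_prev)
    if th2 is not None:
        th3, ok3, extra = _ascent_newton(G, phi, family, data, th2, H_prev,
                                         sig_idx, has_q, p, max_iter=30)
        if ok3:
            return th3, True, it + extra
        th = th3
    if has_q:
        # profile the shape: the fixed-q inner problem is closed form and
        # well conditioned even on the flat large-|q| likelihood ridge
        th4, ok4, extra = _profile_solve(G, phi, family, data, init, H_prev,
                                         sig_idx, p)
        if ok4:
            return th4, True, it + extra
    converged = bool(np.all(np.isfinite(th)) and _within_tol(G(th), has_q))
    return th, converged, it


def _profile_solve(G, phi, family, data, init, H_prev, sig_idx, p,
                   q_bounds=(-5.0, 16.0)):
    """Maximize the penalized likelihood by scalar search over the gg
    shape q, solving the remaining coordinates by frozen-q Newton at
    each trial value, then polish jointly."""
    state = {"best": None, "best_phi": -np.inf}

    def negprof(qv: float) -> float:
        x0 = (state["best"] if state["best"] is not None else init).copy()
        x0[-1] = qv
        thq, okq, _ = _ascent_newton(G, phi, family, data, x0, H_prev,
                                     sig_idx, True, p, max_iter=60, freeze_q=True)
        val = phi(thq) if okq and np.all(np.isfinite(thq)) else -np.inf
        if val > state["best_phi"]:
            state["best"], state["best_phi"] = thq, val
        return -val if np.isfinite(val) else 1e30

    try:
        optimize.minimize_scalar(negprof, bounds=q_bounds, method="bounded",
                                 options={"xatol": 1e-5, "maxiter": 80})
    except (ValueError, FloatingPointError):
        pass
    if state["best"] is None:
        return init, False, 0
    return _ascent_newton(G, phi, family, data, state["best"], H_prev,
                          sig_idx, True, p, max_iter=30)


def _ascent_newton(G, phi, family, data, init, H_prev, sig_idx, has_q, p,
                   max_iter=_MAX_ITER, freeze_q=False):
    th = init.copy()
    g = G(th)
    f = phi(th)
    n_iter = 0
    curv_scale = 1.0
    for n_iter in range(1, max_iter + 1):
        if freeze_q:
            if np.max(np.abs(g[:-1])) < max(_TOL, 1e-12 * curv_scale):
                return th, True, n_iter - 1
        elif _within_tol(g, has_q, curv_scale):
            return th, True, n_iter - 1
        theta_obj = Theta.from_array(th, p, has_q=has_q)
        Htot = sensitivity(family, theta_obj, data) + H_prev
        curv_scale = max(1.0, float(np.max(np.abs(np.diag(Htot)))))
        sig = th[sig_idx]
        # transform to (alpha, beta, eta = log sigma [, q])
        scale = np.ones_like(th)
        scale[sig_idx] = sig
        Ht = Htot * np.outer(scale, scale)
        Ht[sig_idx, sig_idx] -= sig * g[sig_idx]
        gt = scale * g
        # the gg shape equation is only solvable to a finite-difference
        # noise floor; once it is there, pin q and polish the closed-form
        # components so they can reach full tolerance
        pin_q = freeze_q or (has_q and abs(g[-1]) < _TOL_Q
                             and np.max(np.abs(g[:-1])) >= _TOL)
        if pin_q:
            Ht[-1, :] = 0.0
            Ht[:, -1] = 0.0
            Ht[-1, -1] = 1.0
            gt = gt.copy()
            gt[-1] = 0.0
        merit = (lambda v: np.max(np.abs(v[:-1]))) if pin_q else \
            (lambda v: np.max(np.abs(v)))
        step = _pd_solve(Ht, gt)
        if step is None:
            break
        slope = float(gt @ step)
        if slope <= 0:  # not an ascent direction even after ridging
            break
        t, accepted = 1.0, False
        for _ in range(_MAX_HALVING):
            cand = th.copy()
            non_sig = np.arange(th.shape[0]) != sig_idx
            cand[non_sig] = th[non_sig] + t * step[non_sig]
            cand[sig_idx] = sig * np.exp(np.clip(t * step[sig_idx], -20.0, 20.0))
            if np.all(np.isfinite(cand)):
                try:
                    f_new = phi(cand)
                    g_new = G(cand)
                except (ValueError, FloatingPointError):
                    f_new, g_new = np.nan, None
                # Armijo ascent on phi; near the root (where phi is flat to
                # rounding) fall back to decreasing the estimating function
                if np.isfinite(f_new) and g_new is not None and \
                        np.all(np.isfinite(g_new)) and \
                        (f_new >= f + 1e-4 * t * slope
                         or (merit(g) < 1e-4 and merit(g_new) < merit(g))):
                    th, g, f = cand, g_new, f_new
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
    if freeze_q:
        return th, bool(np.max(np.abs(g[:-1])) < max(_TOL, 1e-12 * curv_scale)), n_iter
    return th, _within_tol(g, has_q, curv_scale), n_iter


def _pd_solve(H: np.ndarray, g: np.ndarray) -> np.ndarray | None:
    """Solve H x = g with H forced positive definite by an increasing
    ridge proportional to trace/dim."""
    dim = H.shape[0]
    base = _RIDGE * max(abs(np.trace(H)) / dim, 1.0)
    ridge = 0.0
    for _ in range(40):
        try:
            c, low = linalg.cho_factor(H + ridge * np.eye(dim))
            x = linalg.cho_solve((c, low), g)
            if np.all(np.isfinite(x)):
                return x
        except (linalg.LinAlgError, ValueError):
            pass
        ridge = base if ridge == 0.0 else ridge * 10.0
        if ridge > 1e12 * base:
            return None
    return None


def _fallback_optimize(family, data, init, H_prev, theta_prev):
    """L-BFGS-B on the negative penalized log-likelihood over
    (alpha, beta, log sigma [, q])."""
    p = data.p
    has_q = family.free_q
    sig_idx = p + 1

    def to_nat(x):
        v = x.copy()
        v[sig_idx] = np.exp(np.clip(x[sig_idx], -30, 30))
        return v

    def objective(x):
        v = to_nat(x)
        th = Theta.from_array(v, p, has_q=has_q)
        pen = 0.5 * (v - theta_prev) @ H_prev @ (v - theta_prev)
        val = -(loglik(family, th, data) - pen)
        grad_nat = -(score(family, th, data) + H_prev @ (theta_prev - v))
        grad = grad_nat.copy()
        grad[sig_idx] = grad_nat[sig_idx] * v[sig_idx]
        if not np.isfinite(val):
            return 1e30, np.zeros_like(grad)
        return val, grad

    x0 = init.copy()
    x0[sig_idx] = np.log(max(init[sig_idx], 1e-8))
    try:
        res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 300})
    except (ValueError, FloatingPointError):
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    return to_nat(res.x)


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def _default_init(family: ErrorFamily, data: SiteData) -> np.ndarray:
    logy = np.log(data.y)
    events = data.delta == 1
    sigma0 = float(np.std(logy[events])) if events.sum() >= 2 else float(np.std(logy))
    sigma0 = max(sigma0, 0.05)
    head = np.concatenate(([float(np.mean(logy))], np.zeros(data.p), [sigma0]))
    if family.free_q:
        return np.concatenate((head, [1.0]))
    return head


def _summary_at(family: ErrorFamily, theta: Theta, data: SiteData) -> SiteSummary:
    return SiteSummary(theta_hat=theta,
                       H=sensitivity(family, theta, data),
                       V=variability(family, theta, data),
                       n=data.n)


def fit_local(family: ErrorFamily, data: SiteData, init: Theta | None = None):
    """Local maximum-likelihood fit of one site.

    Returns ``(theta_hat, summary, converged)``.  Non-convergence is
    reported through the flag, never an exception, so simulation
    harnesses can count failures.  A free-shape generalized-gamma fit is
    initialized at the local Weibull estimate with q0 = 1, with restarts
    from the log-normal estimate and q0 = +/-0.5 if that path diverges.
    """
    if data.n_events == 0:
        raise ValueError("no events: cannot fit an AFT model to fully censored data")
    if data.n <= family.n_params(data.p):
        raise ValueError("sample size must exceed the number of parameters")

    inits: list[np.ndarray] = []
    if init is not None:
        inits.append(init.to_array())
    elif family.free_q:
        inits.extend(_gg_inits(data))
    else:
        inits.append(_default_init(family, data))

    best = None
    for x0 in inits:
        th_vec, ok, n_iter = _solve_equation(family, data, x0)
        if ok:
            theta = Theta.from_array(th_vec, data.p, has_q=family.free_q)
            return theta, _summary_at(family, theta, data), True
        if best is None:
            best = (th_vec, n_iter)
    th_vec, n_iter = best
    if th_vec[data.p + 1] <= 0 or not np.all(np.isfinite(th_vec)):
        th_vec = inits[0]
    theta = Theta.from_array(th_vec, data.p, has_q=family.free_q)
    logger.warning("local fit failed to converge (n=%d, family=%s)", data.n, family.name)
    return theta, _summary_at(family, theta, data), False


def _gg_inits(data: SiteData) -> list[np.ndarray]:
    inits = []
    try:
        th_w, _, ok_w = fit_local(ErrorFamily("weibull"), data)
        if ok_w:
            inits.append(np.concatenate((th_w.to_array(), [1.0])))
    except ValueError:
        pass
    try:
        th_ln, _, ok_ln = fit_local(ErrorFamily("lognormal"), data)
        if ok_ln:
            base = th_ln.to_array()
            inits.append(np.concatenate((base, [0.5])))
            inits.append(np.concatenate((base, [-0.5])))
    except ValueError:
        pass
    if not inits:
        inits.append(_default_init(ErrorFamily("gg"), data))
    return inits


def renew(state: CaftaState | None, family: ErrorFamily, data: SiteData) -> CaftaState:
    """Absorb one more site into the collaborative state.

    With no prior state (or a k=0 state) this reduces to the local fit.
    On non-convergence the returned state is flagged and the cumulative
    matrices are left untouched.
    """
    if state is None or state.k == 0:
        theta, summary, ok = fit_local(family, data)
        return CaftaState.from_summary(summary, converged=ok)
    theta_prev = state.theta_hat.to_array()
    th_vec, ok, n_iter = _solve_equation(family, data, theta_prev.copy(),
                                         H_prev=state.H_cum, theta_prev=theta_prev)
    if not ok:
        logger.warning("renewable update failed at site %d", state.k + 1)
        return replace(state, converged=False, n_iter_last=n_iter)
    theta = Theta.from_array(th_vec, data.p, has_q=family.free_q)
    H_k = sensitivity(family, theta, data)
    V_k = variability(family, theta, data)
    return CaftaState(theta_hat=theta,
                      H_cum=state.H_cum + H_k,
                      V_cum=state.V_cum + V_k,
                      N_cum=state.N_cum + data.n,
                      k=state.k + 1,
                      converged=state.converged,
                      n_iter_last=n_iter)


def sandwich_cov(state_or_H, V: np.ndarray | None = None) -> np.ndarray:
    """Robust covariance H^-1 V H^-T from cumulative matrices, computed
    through linear solves (no explicit inverse)."""
    if V is None:
        H, V = state_or_H.H_cum, state_or_H.V_cum
    else:
        H = state_or_H
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"cumulative sensitivity matrix is ill-conditioned (cond={cond:.3g})")
    inner = linalg.solve(H, V, assume_a="sym")
    cov = linalg.solve(H, inner.T, assume_a="sym").T
    return 0.5 * (cov + cov.T)


def run_cafta(family: ErrorFamily, sites: list[SiteData],
              order: str | list[int] = "given") -> FitResult:
    """Run the sequential collaborative procedure over all sites.

    ``order`` is ``"given"`` (the list order), ``"events"`` (descending
    event count, the recommended default for stability) or an explicit
    permutation.  The final log-likelihood is a plug-in second pass: the
    final estimate is broadcast and each site contributes its scalar
    log-likelihood value, keeping the exchange summary-level.
    """
    if len(sites) == 0:
        raise ValueError("at least one site is required")
    idx = _site_order(sites, order)
    first = sites[idx[0]]
    theta1, summary1, ok1 = fit_local(family, first)
    if not ok1:
        raise ConvergenceError("first-site fit failed; no valid initialization")
    state = CaftaState.from_summary(summary1)
    absorbed = [idx[0]]
    failed: list[int] = []
    total_iter = 0
    for j in idx[1:]:
        new_state = renew(state, family, sites[j])
        total_iter += new_state.n_iter_last
        if new_state.k == state.k:  # update failed, matrices untouched
            failed.append(j)
        else:
            absorbed.append(j)
        state = new_state
    converged = state.converged and not failed
    theta = state.theta_hat
    cov_model = _safe_inverse(state.H_cum)
    cov_sand = sandwich_cov(state.H_cum, state.V_cum)
    se_model = _safe_sqrt_diag(cov_model)
    se_sand = _safe_sqrt_diag(cov_sand)
    # plug-in pass: broadcast the final estimate, collect scalar site log-likelihoods
    ll = float(sum(loglik(family, theta, sites[j]) for j in absorbed))
    dim = theta.dim
    with np.errstate(divide="ignore", invalid="ignore"):
        z = theta.to_array() / se_model
    return FitResult(theta_hat=theta, cov_model=cov_model, cov_sandwich=cov_sand,
                     se_model=se_model, se_sandwich=se_sand, z_scores=z,
                     loglik=ll, aic=-2.0 * ll + 2.0 * dim, n_total=state.N_cum,
                     converged=converged, n_iter=total_iter, n_sites=state.k,
                     failed_sites=failed)


def _site_order(sites: list[SiteData], order) -> list[int]:
    if isinstance(order, str):
        if order == "given":
            return list(range(len(sites)))
        if order == "events":
            return order_by_events(sites)
        raise ValueError(f"unknown site order {order!r}")
    idx = list(order)
    if sorted(idx) != list(range(len(sites))):
        raise ValueError("explicit order must be a permutation of the site indices")
    return idx


def order_by_events(sites: list[SiteData]) -> list[int]:
    """Site indices sorted by descending event count (stable)."""
    return sorted(range(len(sites)), key=lambda j: -sites[j].n_events)


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    inv = linalg.solve(H, np.eye(H.shape[0]), assume_a="sym")
    return 0.5 * (inv + inv.T)


def _safe_sqrt_diag(cov: np.ndarray) -> np.ndarray:
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)
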