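"""Error-distribution kernels and likelihood machinery for parametric AFT models.

The accelerated failure time (AFT) model specifies

    log T = alpha + X' beta + sigma * W,

where the standardized error W follows one of four parametric families:

* ``weibull``      — standard extreme-value density  f(w) = exp(w - e^w)
* ``loglogistic``  — standard logistic density       f(w) = e^w (1 + e^w)^-2
* ``lognormal``    — standard normal density
* ``gg``           — generalized gamma with shape q, which nests the
  Weibull (q = 1) and log-normal (q = 0) models.

For a right-censored observation (y, delta, x) with standardized residual
w = (log y - alpha - x'beta) / sigma, the per-subject log-likelihood is

    l = delta * (log f(w) - log sigma) + (1 - delta) * log S(w),

with S(w) the upper tail of f.  This module provides vectorized kernels
(log-density, log-survival and their w-derivatives), the summed
log-likelihood, the analytic score, the sensitivity matrix H (observed
information, the negative Hessian of the log-likelihood) and the
variability matrix V (sum of per-subject score outer products).

Everything is computed on the log scale; the generalized-gamma
normalizing constant uses log-gamma, never Gamma(q^-2) directly.  Shape
derivatives of the generalized gamma (the q direction) use central
finite differences; all other derivatives are closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "ErrorFamily",
    "Theta",
    "SiteData",
    "log_density",
    "log_survival",
    "loglik",
    "per_subject_loglik",
    "score",
    "per_subject_scores",
    "sensitivity",
    "variability",
]

_FAMILY_NAMES = ("weibull", "loglogistic", "lognormal", "gg")

# |q| below this, generalized-gamma kernels switch to a smooth small-q
# expansion around the normal limit so that finite differences in q
# remain well defined across q = 0.
_GG_SMALL_Q = 1e-3

# clip on q*w before exponentiation inside the incomplete-gamma argument
_EXP_CLIP = 700.0

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ErrorFamily:
    """An AFT error distribution.

    For the generalized gamma, ``q`` may be fixed here (a restricted
    model with known shape, as used by the goodness-of-fit test) or left
    ``None``, in which case the shape is a free parameter carried by
    :class:`Theta`.
    """

    name: str
    q: float | None = None

    def __post_init__(self) -> None:
        if self.name not in _FAMILY_NAMES:
            raise ValueError(f"unknown family {self.name!r}; choose from {_FAMILY_NAMES}")
        if self.name != "gg" and self.q is not None:
            raise ValueError(f"shape q is only meaningful for the gg family, not {self.name!r}")
        if self.q is not None and not np.isfinite(self.q):
            raise ValueError("shape q must be finite")

    @property
    def free_q(self) -> bool:
        """True when the generalized-gamma shape is an estimated parameter."""
        return self.name == "gg" and self.q is None

    def n_params(self, p: int) -> int:
        """Dimension of theta for this family with p covariates."""
        return p + 3 if self.free_q else p + 2


@dataclass
class Theta:
    """AFT parameter vector: location intercept, regression coefficients,
    scale, and (free generalized gamma only) the shape q."""

    alpha: float
    beta: np.ndarray
    sigma: float
    q: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.sigma <= 0:
            raise ValueError(f"scale sigma must be positive, got {self.sigma}")

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def dim(self) -> int:
        return self.p + 2 + (0 if self.q is None else 1)

    def to_array(self) -> np.ndarray:
        head = np.concatenate(([self.alpha], self.beta, [self.sigma]))
        if self.q is None:
            return head
        return np.concatenate((head, [self.q]))

    @classmethod
    def from_array(cls, arr: np.ndarray, p: int, has_q: bool = False) -> "Theta":
        arr = np.asarray(arr, dtype=float)
        expected = p + 2 + (1 if has_q else 0)
        if arr.shape != (expected,):
            raise ValueError(f"expected parameter vector of length {expected}, got {arr.shape}")
        q = float(arr[p + 2]) if has_q else None
        return cls(alpha=float(arr[0]), beta=arr[1 : p + 1].copy(),
                   sigma=float(arr[p + 1]), q=q)

    def names(self, covariates: list[str] | None = None) -> list[str]:
        if covariates is None:
            covariates = [f"x{i + 1}" for i in range(self.p)]
        out = ["alpha"] + list(covariates) + ["sigma"]
        if self.q is not None:
            out.append("q")
        return out


@dataclass
class SiteData:
    """One site's right-censored sample.

    ``y`` are observed times (minimum of event and censoring time, all
    strictly positive), ``delta`` the 0/1 event indicators and ``X`` the
    n-by-p covariate matrix.
    """

    y: np.ndarray
    delta: np.ndarray
    X: np.ndarray
    covariate_names: list[str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            if self.X.shape[1] == self.y.shape[0]:  # 1-covariate row vector
                self.X = self.X.T
            else:
                raise ValueError("X row count does not match length of y")
        if self.delta.shape != self.y.shape:
            raise ValueError("delta and y must have the same length")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite values in survival data")
        if np.any(self.y <= 0):
            bad = np.flatnonzero(self.y <= 0)
            raise ValueError(f"observed times must be > 0; offending rows {bad.tolist()[:10]}")
        if not np.all(np.isin(self.delta, (0.0, 1.0))):
            bad = np.flatnonzero(~np.isin(self.delta, (0.0, 1.0)))
            raise ValueError(f"event indicator must be 0 or 1; offending rows {bad.tolist()[:10]}")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())


# ---------------------------------------------------------------------------
# scalar-family kernels: log f, log S and the w-derivatives
#   g(w)  = d/dw log f(w)
#   gp(w) = d/dw g(w)
# censored-term derivatives follow from s = d/dw log S = -f/S and
# s' = s*g - s**2, shared across families.
# ---------------------------------------------------------------------------


def _log_gamma_upper(a: float, u: np.ndarray) -> np.ndarray:
    """log of the regularized upper incomplete gamma Q(a, u), with an
    asymptotic fallback where Q underflows."""
    shape = np.shape(u)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    with np.errstate(divide="ignore"):
        out = np.log(special.gammaincc(a, u))
    bad = ~np.isfinite(out)
    if np.any(bad):
        ub = u[bad]
        # Q(a,u) ~ u^(a-1) e^-u / Gamma(a) for u >> a
        out[bad] = (a - 1.0) * np.log(ub) - ub - special.gammaln(a)
    return out.reshape(shape)


def _log_gamma_lower(a: float, u: np.ndarray) -> np.ndarray:
    """log of the regularized lower incomplete gamma P(a, u), with a
    small-u fallback where P underflows."""
    shape = np.shape(u)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    with np.errstate(divide="ignore"):
        out = np.log(special.gammainc(a, u))
    bad = ~np.isfinite(out)
    if np.any(bad):
        ub = np.maximum(u[bad], 1e-300)
        # P(a,u) ~ u^a e^-u / Gamma(a+1) for u -> 0
        out[bad] = a * np.log(ub) - ub - special.gammaln(a + 1.0)
    return out.reshape(shape)


def _gg_logf(w: np.ndarray, q: float) -> np.ndarray:
    if abs(q) < _GG_SMALL_Q:
        # smooth expansion around the normal (q=0) limit, O(q^3) accurate
        return (-_LOG_SQRT_2PI - 0.5 * w**2 - q * w**3 / 6.0
                - q * q * (w**4 / 24.0 + 1.0 / 12.0))
    a = q ** -2
    qw = q * w
    e = np.exp(np.clip(qw, -_EXP_CLIP, _EXP_CLIP))
    return np.log(abs(q)) + a * np.log(a) - special.gammaln(a) + a * (qw - e)


def _gg_logS(w: np.ndarray, q: float) -> np.ndarray:
    if q == 0.0:
        return special.log_ndtr(-w)
    if abs(q) < _GG_SMALL_Q:
        # Edgeworth-corrected normal tail; z -> w as q -> 0, smooth in q.
        z = np.expm1(np.clip(q * w, -_EXP_CLIP, _EXP_CLIP)) / q
        log_tail = special.log_ndtr(-z)
        hazard = np.exp(np.clip(-0.5 * z**2 - _LOG_SQRT_2PI - log_tail, None, _EXP_CLIP))
        corr = np.clip((q / 3.0) * (z**2 - 1.0) * hazard, -0.9, 10.0)
        return log_tail + np.log1p(corr)
    a = q ** -2
    u = a * np.exp(np.clip(q * w, -_EXP_CLIP, _EXP_CLIP))
    if q > 0:
        return _log_gamma_upper(a, u)
    return _log_gamma_lower(a, u)


def _kernels(name: str, w: np.ndarray, q: float | None):
    """Return (log f, log S, g, g') for the named family at w."""
    w = np.asarray(w, dtype=float)
    if name == "weibull" or (name == "gg" and q == 1.0):
        ew = np.exp(np.clip(w, None, _EXP_CLIP))
        return w - ew, -ew, 1.0 - ew, -ew
    if name == "loglogistic":
        sig = special.expit(w)
        log1pe = np.logaddexp(0.0, w)
        return w - 2.0 * log1pe, -log1pe, 1.0 - 2.0 * sig, -2.0 * sig * (1.0 - sig)
    if name == "lognormal" or (name == "gg" and q == 0.0):
        logf = -0.5 * w**2 - _LOG_SQRT_2PI
        return logf, special.log_ndtr(-w), -w, np.full_like(w, -1.0)
    if name == "gg":
        if q is None:
            raise ValueError("gg kernels require a shape value q")
        qw = np.clip(q * w, -_EXP_CLIP, _EXP_CLIP)
        g = -np.expm1(qw) / q
        gp = -np.exp(qw)
        return _gg_logf(w, q), _gg_logS(w, q), g, gp
    raise ValueError(f"unknown family {name!r}")


def _family_q(family: ErrorFamily, theta: Theta | None = None) -> float | None:
    if family.name != "gg":
        return None
    if theta is not None and theta.q is not None:
        return theta.q
    if family.q is not None:
        return family.q
    raise ValueError("generalized gamma requires a shape q (in theta or in the family)")


def _check_w(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("w must be finite")
    return w


def log_density(family: ErrorFamily, w) -> np.ndarray | float:
    """log f(w) of the standardized error under ``family``."""
    w = _check_w(w)
    logf, _, _, _ = _kernels(family.name, w, _family_q(family))
    return logf if logf.ndim else float(logf)


def log_survival(family: ErrorFamily, w) -> np.ndarray | float:
    """log S(w) = log integral of f over (w, inf)."""
    w = _check_w(w)
    _, logS, _, _ = _kernels(family.name, w, _family_q(family))
    return logS if logS.ndim else float(logS)


# ---------------------------------------------------------------------------
# likelihood, score, information
# ---------------------------------------------------------------------------


def _check_args(family: ErrorFamily, theta: Theta, data: SiteData) -> None:
    if theta.p != data.p:
        raise ValueError(f"theta has {theta.p} coefficients but data has {data.p} covariates")
    if family.free_q and theta.q is None:
        raise ValueError("free generalized gamma requires theta.q")


def _residuals(theta: Theta, data: SiteData) -> np.ndarray:
    return (np.log(data.y) - theta.alpha - data.X @ theta.beta) / theta.sigma


def per_subject_loglik(family: ErrorFamily, theta: Theta, data: SiteData,
                       q_override: float | None = None) -> np.ndarray:
    """Vector of per-subject log-likelihood contributions."""
    _check_args(family, theta, data)
    q = q_override if q_override is not None else _family_q(family, theta)
    w = _residuals(theta, data)
    logf, logS, _, _ = _kernels(family.name, w, q)
    d = data.delta
    return d * (logf - np.log(theta.sigma)) + (1.0 - d) * logS


def loglik(family: ErrorFamily, theta: Theta, data: SiteData) -> float:
    """Full right-censored log-likelihood of the sample at theta."""
    return float(per_subject_loglik(family, theta, data).sum())


def _psi_terms(family: ErrorFamily, theta: Theta, data: SiteData,
               q_override: float | None = None):
    """Shared pieces of score/information: residuals w, and per-subject
    psi = delta*g + (1-delta)*s and its w-derivative, where s = dlogS/dw."""
    q = q_override if q_override is not None else _family_q(family, theta)
    w = _residuals(theta, data)
    with np.errstate(over="ignore", invalid="ignore"):
        logf, logS, g, gp = _kernels(family.name, w, q)
        s = -np.exp(np.clip(logf - logS, None, _EXP_CLIP))
        sp = s * g - s * s
        d = data.delta
        psi = d * g + (1.0 - d) * s
        psip = d * gp + (1.0 - d) * sp
    return w, psi, psip


def _q_step(q: float, scale: float = 1e-4) -> float:
    # the incomplete-gamma tail carries ~1e-8 evaluation roughness at
    # large shape q^-2; steps below ~1e-4 amplify it past the
    # central-difference truncation error
    return scale * max(1.0, abs(q))


def _per_subject_q_scores(family: ErrorFamily, theta: Theta, data: SiteData) -> np.ndarray:
    """Central finite difference of the per-subject log-likelihood in q."""
    q = theta.q if theta.q is not None else _family_q(family)
    h = _q_step(q)
    up = per_subject_loglik(family, theta, data, q_override=q + h)
    dn = per_subject_loglik(family, theta, data, q_override=q - h)
    return (up - dn) / (2.0 * h)


def per_subject_scores(family: ErrorFamily, theta: Theta, data: SiteData,
                       q_override: float | None = None) -> np.ndarray:
    """n-by-dim matrix of per-subject score contributions U_i(theta).

    Derivatives with respect to (alpha, beta, sigma) are closed form for
    every family; the generalized-gamma shape column is a central finite
    difference of the per-subject log-likelihood.  When ``q_override``
    is given, only the (alpha, beta, sigma) columns are returned,
    evaluated at that fixed shape.
    """
    _check_args(family, theta, data)
    w, psi, _ = _psi_terms(family, theta, data, q_override=q_override)
    sig = theta.sigma
    u_alpha = -psi / sig
    u_beta = u_alpha[:, None] * data.X
    u_sigma = -(psi * w + data.delta) / sig
    cols = [u_alpha[:, None], u_beta, u_sigma[:, None]]
    if theta.q is not None and q_override is None:
        cols.append(_per_subject_q_scores(family, theta, data)[:, None])
    return np.hstack(cols)


def score(family: ErrorFamily, theta: Theta, data: SiteData,
          q_override: float | None = None) -> np.ndarray:
    """Score vector U(theta) = gradient of the log-likelihood."""
    return per_subject_scores(family, theta, data, q_override=q_override).sum(axis=0)


def _sensitivity_core(family: ErrorFamily, theta: Theta, data: SiteData,
                      q_override: float | None = None) -> np.ndarray:
    """Observed information over (alpha, beta, sigma), closed form."""
    w, psi, psip = _psi_terms(family, theta, data, q_override=q_override)
    sig2 = theta.sigma ** 2
    Z = np.hstack([np.ones((data.n, 1)), data.X])
    H_zz = -(Z * psip[:, None]).T @ Z / sig2
    cross = -(psip * w + psi)
    H_zs = (Z * cross[:, None]).sum(axis=0) / sig2
    H_ss = -(psip * w**2 + 2.0 * psi * w + data.delta).sum() / sig2
    d0 = Z.shape[1]
    H = np.empty((d0 + 1, d0 + 1))
    H[:d0, :d0] = H_zz
    H[:d0, d0] = H_zs
    H[d0, :d0] = H_zs
    H[d0, d0] = H_ss
    return H


def sensitivity(family: ErrorFamily, theta: Theta, data: SiteData) -> np.ndarray:
    """Sensitivity matrix H(theta): the observed information, i.e. the
    negative Hessian of the log-likelihood.  Symmetric; positive definite
    in a neighborhood of the maximum."""
    _check_args(family, theta, data)
    d0 = data.p + 2
    if theta.q is None:
        return _sensitivity_core(family, theta, data)
    # free shape: closed-form core block, finite-difference shape row
    q = theta.q
    h = _q_step(q, 5e-4)
    H = np.empty((d0 + 1, d0 + 1))
    H[:d0, :d0] = _sensitivity_core(family, theta, data)

    def _score_at(qv: float) -> np.ndarray:
        core = per_subject_scores(family, theta, data, q_override=qv).sum(axis=0)
        hq = _q_step(qv)
        lu = per_subject_loglik(family, theta, data, q_override=qv + hq).sum()
        ld = per_subject_loglik(family, theta, data, q_override=qv - hq).sum()
        return np.concatenate([core, [(lu - ld) / (2.0 * hq)]])

    q_row = -(_score_at(q + h) - _score_at(q - h)) / (2.0 * h)
    H[d0, :] = q_row
    H[:, d0] = q_row
    H[d0, d0] = q_row[d0]
    return 0.5 * (H + H.T)


def variability(family: ErrorFamily, theta: Theta, data: SiteData) -> np.ndarray:
    """Variability matrix V(theta): sum of per-subject score outer
    products, symmetric positive semi-definite."""
    U = per_subject_scores(family, theta, data)
    return U.T @ U
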