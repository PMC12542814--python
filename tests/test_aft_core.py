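"""Error-distribution kernels and likelihood derivative machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from cafta import (
    ErrorFamily,
    SiteData,
    Theta,
    log_density,
    log_survival,
    loglik,
    score,
    sensitivity,
    variability,
)
from cafta.aft_core import per_subject_loglik, per_subject_scores

from conftest import ALL_FAMILIES


# ---------------------------------------------------------------- kernels


@pytest.mark.parametrize("family, w, expected", [
    (ErrorFamily("weibull"), 0.0, -1.0),                      # w - e^w at 0
    (ErrorFamily("lognormal"), 0.0, -0.5 * np.log(2 * np.pi)),
    (ErrorFamily("loglogistic"), 0.0, -np.log(4.0)),          # log(1/(1+1)^2)
])
def test_log_density_closed_forms(family, w, expected):
    assert log_density(family, w) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("family, w, expected", [
    (ErrorFamily("weibull"), 0.0, -1.0),                      # S(0) = e^{-1}
    (ErrorFamily("loglogistic"), 0.0, np.log(0.5)),
])
def test_log_survival_closed_forms(family, w, expected):
    assert log_survival(family, w) == pytest.approx(expected, abs=1e-12)


def test_gg_nests_weibull_exactly():
    w = np.linspace(-5, 5, 101)
    gg1 = ErrorFamily("gg", q=1.0)
    wb = ErrorFamily("weibull")
    assert np.max(np.abs(log_density(gg1, w) - log_density(wb, w))) < 1e-10
    assert np.max(np.abs(log_survival(gg1, w) - log_survival(wb, w))) < 1e-10
    assert log_survival(gg1, 0.7) == pytest.approx(log_survival(wb, 0.7), abs=1e-12)


@pytest.mark.parametrize("q, tol", [(1e-4, 2.5e-3), (-1e-4, 2.5e-3),
                                    (1e-5, 1e-3), (-1e-5, 1e-3)])
def test_gg_approaches_lognormal_as_q_vanishes(q, tol):
    # the leading deviation from the normal limit is q*w^3/6
    w = np.linspace(-5, 5, 41)
    gg = ErrorFamily("gg", q=q)
    ln = ErrorFamily("lognormal")
    assert np.max(np.abs(log_density(gg, w) - log_density(ln, w))) < tol
    assert np.max(np.abs(log_survival(gg, w) - log_survival(ln, w))) < 5 * tol


@pytest.mark.parametrize("family", ALL_FAMILIES, ids=str)
def test_density_normalizes_to_one(family):
    total, _ = integrate.quad(lambda w: np.exp(log_density(family, w)),
                              -np.inf, np.inf, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("family", ALL_FAMILIES, ids=str)
@pytest.mark.parametrize("w0", [-1.2, 0.4, 1.3])
def test_log_survival_matches_quadrature(family, w0):
    tail, _ = integrate.quad(lambda w: np.exp(log_density(family, w)),
                             w0, np.inf, limit=200)
    assert log_survival(family, w0) == pytest.approx(np.log(tail), abs=1e-8)


@pytest.mark.parametrize("family", ALL_FAMILIES, ids=str)
def test_survival_derivative_is_negative_hazard(family):
    # d/dw log S(w) = -f(w)/S(w), checked by central differences
    w = np.linspace(-3, 3, 25)
    h = 1e-6
    fd = (log_survival(family, w + h) - log_survival(family, w - h)) / (2 * h)
    expected = -np.exp(log_density(family, w) - log_survival(family, w))
    assert np.max(np.abs(fd - expected)) < 1e-5 * np.max(np.abs(expected))


def test_nonfinite_w_rejected():
    with pytest.raises(ValueError):
        log_density(ErrorFamily("weibull"), np.nan)
    with pytest.raises(ValueError):
        log_survival(ErrorFamily("gg", q=0.5), np.inf)


def test_family_validation():
    with pytest.raises(ValueError):
        ErrorFamily("gamma")
    with pytest.raises(ValueError):
        ErrorFamily("weibull", q=1.0)   # q only for gg
    with pytest.raises(ValueError):
        ErrorFamily("gg", q=np.inf)


# ------------------------------------------------------------- likelihood


def test_loglik_single_subject_lognormal():
    # y = 1, alpha = 0, sigma = 1 gives w = 0: standard normal log-density
    data = SiteData(np.array([1.0]), np.array([1.0]), np.zeros((1, 0)))
    fam = ErrorFamily("lognormal")
    base = -0.5 * np.log(2 * np.pi)
    assert loglik(fam, Theta(0.0, np.zeros(0), 1.0), data) == pytest.approx(base)
    assert loglik(fam, Theta(0.0, np.zeros(0), 2.0), data) == pytest.approx(
        base - np.log(2.0))


def test_loglik_matches_survival_parameterization(small_censored_site):
    """Same formula through the time-scale distribution: the observed-time
    density under the Weibull AFT is weibull_min(1/sigma, scale=e^{mu}),
    whose log-pdf differs from the log-residual density by the +log y
    Jacobian."""
    data = small_censored_site
    theta = Theta(0.25, np.array([0.1, -0.2, 0.25]), 0.9)
    mu = theta.alpha + data.X @ theta.beta
    dist = stats.weibull_min(1.0 / theta.sigma, scale=np.exp(mu))
    oracle = np.sum(data.delta * (dist.logpdf(data.y) + np.log(data.y))
                    + (1 - data.delta) * dist.logsf(data.y))
    ours = loglik(ErrorFamily("weibull"), theta, data)
    assert ours == pytest.approx(oracle, abs=1e-8)


def test_loglik_input_validation(small_censored_site):
    with pytest.raises(ValueError):
        Theta(0.0, np.zeros(3), -1.0)
    with pytest.raises(ValueError):
        loglik(ErrorFamily("weibull"), Theta(0.0, np.zeros(2), 1.0),
               small_censored_site)  # dimension mismatch


def test_sitedata_validation():
    with pytest.raises(ValueError, match="> 0"):
        SiteData(np.array([1.0, 0.0]), np.array([1.0, 1.0]), np.zeros((2, 1)))
    with pytest.raises(ValueError, match="0 or 1"):
        SiteData(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.zeros((2, 1)))
    with pytest.raises(ValueError):
        SiteData(np.array([1.0, np.nan]), np.array([1.0, 1.0]), np.zeros((2, 1)))


# ------------------------------------------------- derivative consistency


def _theta_for(family):
    beta = np.array([0.15, -0.15, 0.3])
    if family.free_q:
        return Theta(0.3, beta, 0.8, q=0.7)
    return Theta(0.3, beta, 0.8)


DERIV_FAMILIES = [ErrorFamily("weibull"), ErrorFamily("loglogistic"),
                  ErrorFamily("lognormal"), ErrorFamily("gg", q=0.6),
                  ErrorFamily("gg"), ]


@pytest.mark.parametrize("family", DERIV_FAMILIES, ids=str)
def test_score_matches_finite_differences(family, small_censored_site):
    data = small_censored_site
    theta = _theta_for(family)
    v = theta.to_array()
    has_q = theta.q is not None
    analytic = score(family, theta, data)
    fd = np.zeros_like(v)
    for i in range(len(v)):
        h = 1e-6 * max(1.0, abs(v[i]))
        e = np.eye(len(v))[i]
        fd[i] = (loglik(family, Theta.from_array(v + h * e, 3, has_q), data)
                 - loglik(family, Theta.from_array(v - h * e, 3, has_q), data)) / (2 * h)
    denom = np.maximum(1.0, np.abs(fd))
    assert np.max(np.abs(analytic - fd) / denom) < 1e-4


def test_score_single_uncensored_weibull_subject():
    # hand derivative: dl/dalpha = (e^w - 1)/sigma for one event, p = 0
    y, alpha, sig = 1.7, 0.2, 0.9
    data = SiteData(np.array([y]), np.array([1.0]), np.zeros((1, 0)))
    w = (np.log(y) - alpha) / sig
    expected = (np.exp(w) - 1.0) / sig
    got = score(ErrorFamily("weibull"), Theta(alpha, np.zeros(0), sig), data)
    assert got[0] == pytest.approx(expected, rel=1e-10)


@pytest.mark.parametrize("family", DERIV_FAMILIES, ids=str)
def test_sensitivity_symmetric_and_matches_score_differences(family, small_censored_site):
    data = small_censored_site
    theta = _theta_for(family)
    v = theta.to_array()
    has_q = theta.q is not None
    H = sensitivity(family, theta, data)
    assert np.max(np.abs(H - H.T)) < 1e-8
    fd = np.zeros_like(H)
    for i in range(len(v)):
        h = 2e-4 * max(1.0, abs(v[i]))
        e = np.eye(len(v))[i]
        sp = score(family, Theta.from_array(v + h * e, 3, has_q), data)
        sm = score(family, Theta.from_array(v - h * e, 3, has_q), data)
        fd[i] = -(sp - sm) / (2 * h)
    fd = 0.5 * (fd + fd.T)
    assert np.max(np.abs(H - fd) / np.maximum(1.0, np.abs(fd))) < 5e-3


@pytest.mark.parametrize("family", DERIV_FAMILIES, ids=str)
def test_variability_psd_and_consistent_with_score(family, small_censored_site):
    data = small_censored_site
    theta = _theta_for(family)
    V = variability(family, theta, data)
    assert np.max(np.abs(V - V.T)) < 1e-10
    assert np.linalg.eigvalsh(V).min() >= -1e-10
    U = per_subject_scores(family, theta, data)
    assert np.max(np.abs(U.sum(axis=0) - score(family, theta, data))) < 1e-12
    assert per_subject_loglik(family, theta, data).shape == (data.n,)


def test_information_identity_at_mle_large_sample():
    """At the MLE of a large correctly-specified sample, the variability
    matrix estimates the same information as the sensitivity matrix."""
    from cafta import fit_local
    rng = np.random.default_rng(7)
    n, p = 20000, 2
    X = rng.normal(size=(n, p))
    beta = np.array([0.2, -0.3])
    T = np.exp(0.3 + X @ beta + 0.8 * np.log(rng.exponential(size=n)))
    C = rng.uniform(0, 6.0, size=n)
    data = SiteData(np.minimum(T, C), (T <= C).astype(float), X)
    fam = ErrorFamily("weibull")
    theta, summary, ok = fit_local(fam, data)
    assert ok
    dH, dV = np.diag(summary.H), np.diag(summary.V)
    assert np.max(np.abs(dV - dH) / dH) < 0.05
    assert np.linalg.eigvalsh(summary.H).min() > 0


@settings(derandomize=True, max_examples=20, deadline=None)
@given(w=st.floats(-6.0, 6.0),
       q=st.floats(-2.5, 2.5).filter(lambda v: abs(v) > 1e-6))
def test_gg_density_below_one_and_survival_valid(w, q):
    fam = ErrorFamily("gg", q=q)
    ls = log_survival(fam, w)
    assert ls <= 1e-12
    assert np.isfinite(log_density(fam, w))
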