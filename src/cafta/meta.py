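"""Inverse-variance meta-analysis of per-site AFT fits.

The comparator arms of the simulation study: each site is fit by local
maximum likelihood and the coefficient estimates are pooled per
coordinate, either with fixed-effect inverse-variance weights or with
DerSimonian-Laird random-effect weights.  Only converged sites enter
the pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetaInput", "meta_fe", "meta_re"]


@dataclass
class MetaInput:
    """Per-site estimates (K x d), squared standard errors (K x d), and
    a convergence mask of length K."""

    estimates: np.ndarray
    variances: np.ndarray
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.estimates = np.atleast_2d(np.asarray(self.estimates, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if self.estimates.shape != self.variances.shape:
            raise ValueError("estimates and variances must have matching shapes")
        if self.converged is None:
            self.converged = np.ones(self.estimates.shape[0], dtype=bool)
        self.converged = np.asarray(self.converged, dtype=bool)
        if np.any(self.variances[self.converged] <= 0):
            raise ValueError("variances of converged sites must be positive")

    def _usable(self) -> tuple[np.ndarray, np.ndarray]:
        est = self.estimates[self.converged]
        var = self.variances[self.converged]
        if est.shape[0] == 0:
            raise ValueError("no converged sites to pool")
        return est, var


def meta_fe(input: MetaInput) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect pooling: per coordinate, the inverse-variance
    weighted mean with standard error (sum of weights)^(-1/2)."""
    est, var = input._usable()
    w = 1.0 / var
    pooled = (w * est).sum(axis=0) / w.sum(axis=0)
    se = w.sum(axis=0) ** -0.5
    return pooled, se


def meta_re(input: MetaInput) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DerSimonian-Laird random-effect pooling, per coordinate.

    Cochran's Q = sum_j w_j (theta_j - theta_FE)^2 with fixed-effect
    weights; the between-site variance is
    tau^2 = max(0, (Q - (K-1)) / (sum w - sum w^2 / sum w)) and the
    random-effect weights are 1 / (var_j + tau^2).  With a single
    converged site this reduces to the fixed-effect answer, tau^2 = 0.
    """
    est, var = input._usable()
    K = est.shape[0]
    pooled_fe, _ = meta_fe(input)
    if K < 2:
        return pooled_fe, var[0] ** 0.5, np.zeros(est.shape[1])
    w = 1.0 / var
    sw = w.sum(axis=0)
    Q = (w * (est - pooled_fe) ** 2).sum(axis=0)
    denom = sw - (w**2).sum(axis=0) / sw
    tau2 = np.maximum(0.0, (Q - (K - 1)) / denom)
    w_re = 1.0 / (var + tau2)
    pooled = (w_re * est).sum(axis=0) / w_re.sum(axis=0)
    se = w_re.sum(axis=0) ** -0.5
    return pooled, se, tau2
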