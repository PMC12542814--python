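"""Site-data CSV dialect, the JSON summary-exchange format, and reports.

Site files are plain CSV with a header row: required columns ``time``
(observed time, strictly positive) and ``status`` (1 = event,
0 = censored); every remaining column is a numeric covariate, in header
order.  Missing values are rejected.

The exchange message is the only thing that ever leaves a site: the
current estimate, the sensitivity and variability matrices, and the
sample size — no subject-level quantity.  Matrices are serialized
row-major with a dimension header; floats survive a round trip losslessly
(shortest-repr JSON encoding).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aft_core import ErrorFamily, SiteData, Theta
from .estimation import CaftaState, FitResult, SiteSummary

__all__ = [
    "read_site_csv",
    "write_site_csv",
    "ExchangeMessage",
    "write_exchange_message",
    "read_exchange_message",
    "state_to_message",
    "message_to_state",
    "write_report",
]

SCHEMA_VERSION = "1.0"


def read_site_csv(path) -> SiteData:
    """Read one site's data; validates positivity of times, 0/1 status
    and absence of missing values, naming offending rows."""
    df = pd.read_csv(path)
    for col in ("time", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:10]
        raise ValueError(f"{path}: missing values in rows {bad}")
    cov_cols = [c for c in df.columns if c not in ("time", "status")]
    y = df["time"].to_numpy(dtype=float)
    delta = df["status"].to_numpy(dtype=float)
    if np.any(y <= 0):
        bad = df.index[y <= 0].tolist()[:10]
        raise ValueError(f"{path}: observed times must be > 0 (rows {bad})")
    if not np.all(np.isin(delta, (0.0, 1.0))):
        bad = df.index[~np.isin(delta, (0.0, 1.0))].tolist()[:10]
        raise ValueError(f"{path}: status must be 0 or 1 (rows {bad})")
    X = df[cov_cols].to_numpy(dtype=float)
    return SiteData(y=y, delta=delta, X=X, covariate_names=cov_cols)


def write_site_csv(path, data: SiteData) -> None:
    names = data.covariate_names or [f"x{i + 1}" for i in range(data.p)]
    df = pd.DataFrame(data.X, columns=names)
    df.insert(0, "status", data.delta.astype(int))
    df.insert(0, "time", data.y)
    df.to_csv(path, index=False)


@dataclass
class ExchangeMessage:
    """Versioned, JSON-serializable summary-statistic message."""

    family: ErrorFamily
    theta_names: list[str]
    theta: np.ndarray
    H: np.ndarray
    V: np.ndarray
    n: int
    k: int = 1
    site_label: str = ""
    timestamp: str = ""
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = len(self.theta_names)
        return {
            "schema_version": self.schema_version,
            "family": {"name": self.family.name, "q": self.family.q},
            "theta_names": list(self.theta_names),
            "theta": [float(v) for v in self.theta],
            "H": {"dim": d, "row_major": [float(v) for v in np.asarray(self.H).ravel()]},
            "V": {"dim": d, "row_major": [float(v) for v in np.asarray(self.V).ravel()]},
            "n": int(self.n),
            "k": int(self.k),
            "provenance": {"site_label": self.site_label,
                           "timestamp": self.timestamp or
                           _dt.datetime.now(_dt.timezone.utc).isoformat()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExchangeMessage":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {d.get('schema_version')!r}")
        fam = ErrorFamily(d["family"]["name"], d["family"].get("q"))
        names = list(d["theta_names"])
        dim = len(names)
        H = np.asarray(d["H"]["row_major"], dtype=float).reshape(d["H"]["dim"], -1)
        V = np.asarray(d["V"]["row_major"], dtype=float).reshape(d["V"]["dim"], -1)
        if H.shape != (dim, dim) or V.shape != (dim, dim):
            raise ValueError("matrix dimensions do not match theta_names")
        return cls(family=fam, theta_names=names,
                   theta=np.asarray(d["theta"], dtype=float), H=H, V=V,
                   n=d["n"], k=d.get("k", 1),
                   site_label=d.get("provenance", {}).get("site_label", ""),
                   timestamp=d.get("provenance", {}).get("timestamp", ""))


def state_to_message(state: CaftaState, family: ErrorFamily,
                     covariate_names: list[str] | None = None,
                     site_label: str = "") -> ExchangeMessage:
    theta = state.theta_hat
    return ExchangeMessage(family=family,
                           theta_names=theta.names(covariate_names),
                           theta=theta.to_array(), H=state.H_cum, V=state.V_cum,
                           n=state.N_cum, k=state.k, site_label=site_label)


def message_to_state(msg: ExchangeMessage) -> CaftaState:
    p = len(msg.theta_names) - 2 - (1 if "q" in msg.theta_names else 0)
    theta = Theta.from_array(msg.theta, p, has_q="q" in msg.theta_names)
    return CaftaState(theta_hat=theta, H_cum=msg.H.copy(), V_cum=msg.V.copy(),
                      N_cum=msg.n, k=msg.k)


def summary_to_message(summary: SiteSummary, family: ErrorFamily,
                       covariate_names: list[str] | None = None,
                       site_label: str = "") -> ExchangeMessage:
    theta = summary.theta_hat
    return ExchangeMessage(family=family,
                           theta_names=theta.names(covariate_names),
                           theta=theta.to_array(), H=summary.H, V=summary.V,
                           n=summary.n, site_label=site_label)


def write_exchange_message(path, msg: ExchangeMessage) -> None:
    with open(path, "w") as fh:
        json.dump(msg.to_dict(), fh, indent=1)


def read_exchange_message(path) -> ExchangeMessage:
    with open(path) as fh:
        return ExchangeMessage.from_dict(json.load(fh))


_Z975 = 1.959963984540054


def report_frame(fit: FitResult, covariate_names: list[str] | None = None,
                 robust: bool = False) -> pd.DataFrame:
    """Per-parameter report: estimate, exp(estimate), SEs, z, 95% CI."""
    names = fit.theta_hat.names(covariate_names)
    est = fit.theta_hat.to_array()
    se = fit.se_sandwich if robust else fit.se_model
    z = est / se
    return pd.DataFrame({
        "parameter": names,
        "estimate": est,
        "exp_estimate": np.exp(est),
        "se_model": fit.se_model,
        "se_sandwich": fit.se_sandwich,
        "z": z,
        "ci_low": est - _Z975 * se,
        "ci_high": est + _Z975 * se,
    })


def write_report(fit: FitResult, format: str = "text",
                 covariate_names: list[str] | None = None,
                 robust: bool = False) -> str:
    """Render a fit as text, CSV, or JSON."""
    frame = report_frame(fit, covariate_names, robust=robust)
    meta = {"loglik": fit.loglik, "aic": fit.aic, "n_total": fit.n_total,
            "n_sites": fit.n_sites, "converged": fit.converged}
    if format == "csv":
        return frame.to_csv(index=False)
    if format == "json":
        return json.dumps({"parameters": frame.to_dict(orient="records"), **meta},
                          indent=1)
    if format == "text":
        lines = [frame.to_string(index=False, float_format=lambda v: f"{v: .4f}"),
                 "",
                 f"loglik = {fit.loglik:.4f}   AIC = {fit.aic:.4f}   "
                 f"N = {fit.n_total}   sites = {fit.n_sites}   "
                 f"converged = {fit.converged}"]
        return "\n".join(lines)
    raise ValueError(f"unknown report format {format!r}")
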