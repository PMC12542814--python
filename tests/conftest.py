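import logging
import warnings

import numpy as np
import pytest

from cafta import ErrorFamily, SimConfig, SiteData
from cafta.simulation import _generate_replicate, _site_zetas

logging.getLogger("cafta").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message=".*ill-conditioned.*")

TRUE_BETA = np.array([0.15, -0.15, 0.3, 0.1, -0.1, 0.3])
TRUE_ALPHA, TRUE_SIGMA = 0.3, 0.8


def make_sites(family="weibull", event_rate=0.3, seed=0,
               sizes=(500, 300, 100, 50, 50, 50)):
    """One replicate of the six-site multicenter design."""
    cfg = SimConfig(family=family, target_event_rate=event_rate, n_reps=1,
                    seed=seed, site_sizes=sizes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    return _generate_replicate(cfg, _site_zetas(cfg), rng)


def pool(sites):
    return SiteData(np.concatenate([s.y for s in sites]),
                    np.concatenate([s.delta for s in sites]),
                    np.vstack([s.X for s in sites]))


@pytest.fixture(scope="session")
def weibull_sites():
    return make_sites("weibull", 0.3, seed=1)


@pytest.fixture(scope="session")
def weibull_pooled(weibull_sites):
    return pool(weibull_sites)


@pytest.fixture(scope="session")
def small_censored_site():
    """A small mixed event/censoring sample for derivative checks."""
    rng = np.random.default_rng(42)
    n, p = 60, 3
    X = rng.normal(size=(n, p))
    beta = np.array([0.15, -0.15, 0.3])
    T = np.exp(0.3 + X @ beta + 0.8 * np.log(rng.exponential(size=n)))
    C = rng.uniform(0, 4.0, size=n)
    return SiteData(np.minimum(T, C), (T <= C).astype(float), X)


ALL_FAMILIES = [
    ErrorFamily("weibull"),
    ErrorFamily("loglogistic"),
    ErrorFamily("lognormal"),
    ErrorFamily("gg", q=-1.0),
    ErrorFamily("gg", q=0.5),
    ErrorFamily("gg", q=2.53),
]
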