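# cafta — collaborative AFT analysis from site-level summary statistics

Multi-center time-to-event studies usually cannot pool patient-level
records across hospitals or registries.  `cafta` fits **parametric
accelerated failure time (AFT) models** to right-censored survival data
held at K separate clinical sites, exchanging nothing but site-level
summary statistics, and recovers an estimator that is asymptotically
equivalent to the maximum likelihood estimator on the (unavailable)
pooled data.  It is written for biostatisticians running federated
survival analyses and for methodologists studying distributed inference.

## The model and the estimator

The AFT model relates covariates directly to event time:

```
log T = α + Xᵀβ + σ W
```

with intercept α, coefficients β, scale σ > 0, and a standardized error
W following one of four laws: extreme-value (Weibull AFT model),
logistic (log-logistic), normal (log-normal), or the three-parameter
**generalized gamma (GG)** with shape q, which nests the Weibull (q = 1)
and log-normal (q = 0) models.  For a subject with observed time
y = min(T, C) > 0 and event indicator δ, the log-likelihood contribution
is `δ[log f(w) − log σ] + (1 − δ) log S(w)` with w = (log y − α − xᵀβ)/σ.

Sites are visited sequentially.  Site 1 solves its local score equation
U₁(θ) = 0.  Site k receives only the running estimate θ̂ₖ₋₁ and the
cumulative **sensitivity** (observed information) matrices and solves the
renewable estimating equation

```
U_k(θ̂_k) + [Σ_{j<k} H_j(θ̂_j)] (θ̂_{k−1} − θ̂_k) = 0 .
```

Alongside, the cumulative **variability** matrix Σ V_j (per-subject score
outer products) is maintained, giving the model-based covariance
`(Σ H)⁻¹` and the robust sandwich `(Σ H)⁻¹ (Σ V) (Σ H)⁻ᵀ`.  No
subject-level quantity ever crosses a site boundary.

Model choice uses the distributed likelihood-ratio statistic
`Λ = −2[ℓ(θ̂_restricted) − ℓ(θ̂_GG)]`, referred to χ²₁ (5% critical value
3.84), where both log-likelihoods are assembled from scalar per-site
plug-in contributions; non-nested candidates (log-logistic) are compared
by AIC.  Classical fixed-effect and DerSimonian–Laird random-effect
inverse-variance meta-analyses of independent per-site fits are included
as baselines.

## Worked example

Simulate one realization of a six-site study (sites of 500, 300, 100,
50, 50, 50 subjects; Weibull errors; ~50% event rate) and fit it
collaboratively:

```python
import numpy as np
from cafta import ErrorFamily, SimConfig, run_cafta, lrt_gg
from cafta.simulation import _generate_replicate, _site_zetas
from cafta.io import write_report

cfg = SimConfig(family="weibull", target_event_rate=0.5, n_reps=1, seed=12345)
sites = _generate_replicate(cfg, _site_zetas(cfg), np.random.default_rng(12345))
fit = run_cafta(ErrorFamily("weibull"), sites)
print(write_report(fit, "text", [f"x{i+1}" for i in range(6)]))
res = lrt_gg(sites, q0=1.0)
print(f"LRT H0: q=1  lambda = {res.lam:.4f}  p = {res.p_value:.4f}")
```

prints

```
parameter  estimate  exp_estimate  se_model  se_sandwich        z  ci_low  ci_high
    alpha    0.3993        1.4908    0.1181       0.1143   3.3812  0.1678   0.6308
       x1    0.1688        1.1839    0.0381       0.0379   4.4303  0.0941   0.2435
       x2   -0.1642        0.8485    0.0374       0.0368  -4.3958 -0.2375  -0.0910
       x3    0.2065        1.2294    0.0863       0.0895   2.3932  0.0374   0.3756
       x4    0.0159        1.0160    0.1358       0.1335   0.1173 -0.2502   0.2820
       x5   -0.1035        0.9016    0.1224       0.1198  -0.8461 -0.3434   0.1363
       x6    0.1604        1.1740    0.1221       0.1187   1.3134 -0.0790   0.3997
    sigma    0.8116        2.2516    0.0294       0.0296  27.5789  0.7540   0.8693

loglik = -1127.7193   AIC = 2271.4385   N = 1050   sites = 6   converged = True
LRT H0: q=1  lambda = 0.0000  p = 1.0000
```

The true coefficients were (0.15, −0.15, 0.3, 0.1, −0.1, 0.3) with
α = 0.3, σ = 0.8: every 95% interval covers its target, `exp(estimate)`
is the multiplicative effect on event time (x1 stretches time-to-event
by ~18% per unit), and the shape test correctly retains the Weibull
model.

The same analyses run from the shell on CSV site files (columns `time`,
`status`, covariates):

```
cafta fit --family weibull --site site1.csv --site site2.csv --order events
cafta gof --null weibull --site site1.csv --site site2.csv
cafta aic --families weibull,lognormal,loglogistic,gg --site ...
cafta meta --family weibull --site ... [--random-effects]
cafta simulate --family lognormal --event-rate 0.3 --reps 500 --seed 1 --out metrics.csv
```

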