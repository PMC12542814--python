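# Methods

## Model

Parametric accelerated failure time (AFT) regression for right-censored
data: `log T = α + Xᵀβ + σW`, observed as y = min(T, C) > 0 with event
indicator δ = 1{T ≤ C}, censoring noninformative, subjects independent.
The error density f(w) is extreme-value (`weibull`), standard logistic
(`loglogistic`), standard normal (`lognormal`), or generalized gamma
(`gg`) with shape q:

```
f(w; q) = |q| (q⁻²)^{q⁻²} exp[q⁻²(qw − e^{qw})] / Γ(q⁻²),  q ≠ 0,
f(w; 0) = standard normal density.
```

q = 1 recovers the extreme-value law and q → 0 the normal law, so the
Weibull and log-normal AFT models are nested inside the generalized
gamma and can be tested with one degree of freedom.  The full
log-likelihood is `Σ δᵢ[log f(wᵢ) − log σ] + (1 − δᵢ) log S(wᵢ)` with
w = (log y − α − xᵀβ)/σ.  (A printed form of this standardization
elsewhere is ambiguous in operator precedence; we use the standard
reading in which the whole linear predictor is subtracted before
dividing by σ.)  This is the density of log T, i.e. it omits the
parameter-free `−Σδ log y` Jacobian; scores, information matrices, model
comparisons and tests are unaffected.

## Collaborative estimation

Site 1 computes its local MLE.  Site k solves
`U_k(θ) + H_cum (θ̂_{k−1} − θ) = 0`, where H_cum is the running sum of
per-site sensitivity matrices H_j (observed information, evaluated at
each site's own update θ̂_j — never re-evaluated later).  The variability
matrices V_j (sums of per-subject score outer products) accumulate the
same way.  Final inference uses `cov_model = H_cum⁻¹` and
`cov_sandwich = H_cum⁻¹ V_cum H_cum⁻ᵀ` (computed by linear solves).  The
exchanged message (estimate, H, V, sample size, and on request a scalar
plug-in log-likelihood) is the entire cross-site interface; a
serialization test enforces that no array scaling with the number of
subjects appears in it.

The model log-likelihood at the final estimate — needed for AIC and the
likelihood-ratio test — is obtained by one extra summary-level round:
the final θ̂ is broadcast and each site returns its scalar ℓ_k(θ̂).  This
is exact rather than approximate; the alternative (no extra round,
approximating ℓ from stored quantities) was rejected because the test
statistic is the sole consumer and deserves the exact value.

Site ordering is caller-controlled; `order="events"` sorts by descending
event count, the recommended default for numerical stability since the
first site is the only one fit without a curvature anchor.

## Numerical method

All derivatives with respect to (α, β, σ) are closed form for every
family, including the generalized gamma: with g = d log f/dw and
s = d log S/dw = −f/S, the score and Hessian blocks follow from the
chain rule (s′ = s·g − s², shared across families).  Only the gg shape
direction is differentiated numerically (central differences of the
per-subject log-likelihood; step 1e-4·max(1, |q|) for the score,
5e-4 for the Hessian row).  Steps this large are deliberate: the
regularized incomplete-gamma tail carries ~1e-8 evaluation roughness at
extreme shapes a = q⁻², and finer steps amplify that noise past the
truncation error.

The solver is Newton–Raphson on the internal parameterization
(α, β, log σ [, q]): the transformed Hessian is forced positive definite
by an adaptive ridge, the step passes an Armijo backtracking line search
(up to 30 halvings) on the penalized log-likelihood, and σ stays
positive by construction.  Convergence is declared on the natural-scale
estimating function: max-abs below 1e-8 for closed-form components (with
a parameter-resolution backstop of 1e-12 × the largest curvature entry,
relevant only at degenerate scales such as σ → 0), and 5e-3 for the
finite-difference shape component.  The looser shape tolerance is its
achievable noise floor; on the flattest shape ridges (curvature ~0.04 in
q) it bounds the log-likelihood slack below ~1e-4, far below the χ²₁
noise scale of the test that consumes it.  Up to 100 iterations; on
failure, an L-BFGS-B pass on the same objective, then — for free-shape
gg fits — a profile-likelihood fallback: scalar search over q with the
well-conditioned fixed-q inner problem solved by Newton at each trial
value.  Non-convergence is reported through flags (a first-site failure
raises, since the chain has no valid state), and a failed renewable
update leaves the cumulative matrices untouched.

Local fits start at α₀ = mean(log y), β₀ = 0, σ₀ = sd(log y among
events) (floored at 0.05); free-shape gg fits start at the local Weibull
solution with q₀ = 1, with restarts from the log-normal solution and
q₀ = ±0.5.  The gg likelihood genuinely develops flat interior maxima
far from q = 1 in small samples (verified by profile likelihood); these
are legitimate solutions, not pathologies, and the profile fallback
exists to certify them.

Generalized-gamma kernels near q = 0 use a smooth small-|q| branch
(|q| < 1e-3): a fourth-order expansion of the log-density around the
normal limit and an Edgeworth-corrected normal tail for log-survival.
A hard switch to the exact normal branch would zero out finite-difference
q-derivatives inside the window and stall the shape update.  Tail
safety: q·w is clipped at ±700 before exponentiation, the normal tail
uses the complementary log-error-function, the logistic tail uses
log1p-style forms, and underflowing incomplete-gamma tails fall back to
their leading asymptotic terms.

## Synthetic data generator

The generator emulates a six-site transplant-registry-like study: full
samples of N = 1050 drawn i.i.d. and randomly split into sites of
(500, 300, 100, 50, 50, 50).  Covariates: (X1, X2) bivariate normal with
unit variances and covariance 0.3; X3 ~ Bernoulli(0.8); X4 a
four-category variable entered as three dummies, with conditional
probabilities (0.2, 0.2, 0.3, 0.3) given X3 = 0 and, given X3 = 1, the
vector (0.1, 0.2, 0.4, 0.5) normalized by its sum (the raw vector — kept
configurable — sums to 1.2 and cannot parameterize a multinomial as
printed).  True parameters: β = (0.15, −0.15, 0.3, 0.1, −0.1, 0.3)
(X1, X2, X3, and the second to fourth X4 categories), α = 0.3, σ = 0.8.
Censoring is C ~ Uniform(0, ζ), with ζ calibrated by bisection of the
Monte-Carlo event-rate function Ê(ζ) = mean(max(0, 1 − T/ζ)) over a
fixed simulated event-time sample of 10⁵ (tolerance 0.002); the
population event rate is the calibration target, equivalent at these
sample sizes to the realized fraction.  Seeding: one root seed spawns
per-replicate child streams (counter-based), so studies are reproducible
and order-independent across replicates.

What the generator does **not** emulate: covariate measurement error,
informative or administrative censoring patterns, site-level parameter
heterogeneity (available as explicit knobs — per-site event-rate targets
and covariate mean shifts — but off by default), ties, or left
truncation.  Passing tests therefore demonstrate correctness of the
estimator and test under a correctly specified model, not robustness to
misspecification.

## Study harness and metrics

Per replicate the harness fits the pooled-data oracle MLE, the
sequential collaborative estimator (fixed site order, largest first),
and per-site MLEs pooled by fixed-effect inverse variance (and
optionally DerSimonian–Laird random effects; the between-site variance
estimator is DL, the field default, since no specific choice is
canonical here).  Pooling is per coordinate, matching how per-coefficient
metrics are reported.  Metrics over converged replicates: ARB (mean
absolute relative deviation from the oracle estimate, in %), CP
(95% Wald coverage of the truth, model-based SEs), MSE, ASE (mean
estimated SE), ESE (empirical SD), and fails (for meta, a replicate
fails when any site fails).  Failed replicates are excluded from that
method's averages.

Desk-scale problem sizes: the replicated studies in the tests and the
acceptance script use 500 replicates for coverage/ASE quantities and 300
for likelihood-ratio rejection rates — enough for Monte-Carlo standard
errors of ~1 percentage point on coverage and ~1.3 on a 5% rejection
rate, which is the resolution at which the reference values are quoted.

## Known limitations

* The meta-analysis baseline is fitted with the same robust solver as
  everything else, so it converges far more often than a stock
  `survreg`-style fitter would at very low event rates; comparisons that
  hinge on baseline solver failures (e.g. severe meta undercoverage at a
  10% event rate) will not reproduce here — our meta arm is simply
  better behaved, and its coverage stays near nominal.
* The free-shape gg estimating equation is solved to the shape-direction
  noise floor (5e-3), not 1e-8; q̂ on flat ridges is best read together
  with its (large) standard error.
* Left truncation, interval censoring, time-varying covariates, frailty,
  and multivariate (cross-coefficient) meta-analysis are out of scope.
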