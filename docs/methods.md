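# Methods

## Model

`jtdina` couples two measurement models through layered covariance
structure. Response accuracy follows a testlet-DINA model: the log-odds of
success are an item intercept plus an interaction term gated by conjunctive
attribute mastery, plus a person-by-testlet random effect γ. Response times
follow a lognormal model: log seconds are normal with mean ξ_i − τ_n −
Σ_m u_im λ_nm and variance ω_i⁻². Working on the log-time scale makes the
two forms equivalent up to the Jacobian 1/t, which the test suite verifies
against an independent lognormal density to 1e−10 relative error.

Mastery indicators are Bernoulli given a higher-order general ability via
logit P(α_nk = 1) = ν_k θ_n − κ_k with ν_k > 0 for sign identification.
(θ, τ) are bivariate normal with μ_θ = μ_τ = 0 and σ²_θ = 1 fixed; the
covariance is parameterised through the Cholesky factors Δ = [[1, 0],
[φ, ψ]], so the reconstructed Σ_person always has unit ability variance
exactly. Item vectors (β, δ, ξ) are trivariate normal; the RT precision
ω² is a separate independent layer. Each testlet owns a 2×2 covariance for
its paired effects (γ, λ); the same U-matrix drives both sides, which is
what makes the dependence "paired". Four conditional-independence
assumptions follow: α given θ; Y given (α, γ); log T given (τ, λ); and Y
vs log T given all person-side quantities.

Setting every testlet effect to zero (or M = 0) reduces the likelihood
exactly to the JRT-DINA baseline; this reduction is property-tested.

By default each item may belong to at most one testlet, matching the
single-source designs this package targets; `UMatrix(...,
allow_multi_testlet=True)` enables within-item multidimensional testlet
structure (an item loading on several testlet effects), which the
likelihood supports but no bundled design uses.

## Priors

As implemented (all normal second arguments are variances — the
alternative precision reading of ambiguous notation is rejected for
consistency with the explicit covariance matrices used elsewhere):

* (β_i, δ_i, ξ_i) | μ_item, Σ_item ~ N₃(μ_item, Σ_item)
* ω_i⁻² ~ InvGamma(1, 1), i.e. precision ω_i² ~ Gamma(1, 1)
* μ_β ~ N(−2.197, 2); μ_δ ~ N(4.394, 2) truncated positive; μ_ξ ~ N(3, 2)
* Σ_item ~ InvWishart(I₃, 3); each Σ_testlet,m ~ InvWishart(I₂, 2), with
  density ∝ |Σ|^{−(df+p+1)/2} exp(−tr(scale·Σ⁻¹)/2)
* φ ~ N(0, 1); ψ ~ Gamma(1, 1); κ_k ~ N(0, 4); ν_k ~ N(0, 4) truncated
  positive.

The centre of the μ_β/μ_δ hyperpriors corresponds to a guessing probability
of 0.1 and a slip probability of 0.1 on the logit scale
(expit(−2.197) ≈ 0.1, expit(2.197) ≈ 0.9).

## Sampler

Metropolis-within-Gibbs, hand-rolled and fully vectorised over persons and
items:

* **α_nk** — exact Bernoulli full conditional: higher-order prior odds
  times the RA likelihood ratio over items requiring attribute k, other
  attributes held fixed. Because the flipped logit always moves between
  β+tc and β+δ+tc, both softplus fields are precomputed once per sweep.
* **τ_n, ξ_i, λ_nm** — conjugate normal updates (the RT layer is linear
  Gaussian given ω). Their posterior moments are cross-checked in tests
  against brute-force grid integration of the same conditionals.
* **ω_i²** — conjugate gamma. **Σ_item, Σ_testlet,m** — conjugate
  inverse-Wishart via a Bartlett-decomposition sampler (cross-checked
  against scipy's generator). **μ_item** — componentwise normal with
  inverse-CDF truncation for μ_δ. **φ** — conjugate normal regression of τ
  on θ.
* **β_i, δ_i, θ_n, γ_nm, ν_k, κ_k** — adaptive random-walk Metropolis,
  vectorised across the block's units (each unit's conditional is
  independent given the rest). **ψ** — random-walk on the log scale with
  Jacobian correction. Step sizes adapt every 50 burn-in iterations toward
  ~35% acceptance (multiplying by exp(rate − 0.35), clipped), then freeze.
* **β–δ shear move** — the likelihood pins β_i + δ_i for persons mastering
  item i while β_i alone is informed only by non-masters, leaving a strongly
  anti-correlated ridge that coordinatewise walks traverse slowly. A
  per-item proposal β* = β + e, δ* = δ − e leaves every mastery-pattern-1
  response term invariant, so only the η = 0 terms and the trivariate prior
  enter the acceptance ratio.
* **time-location move** — the RT likelihood depends on ξ_i − τ_n only, so
  the common location of time intensities and speeds is a soft ridge pinned
  only by the μ_τ = 0 constraint. A global translation ξ + c, τ + c,
  μ_ξ + c keeps the likelihood and the ξ prior invariant; the ratio
  involves just the τ prior and the μ_ξ hyperprior.
* **(γ_m, Σ_testlet,m) group move** — each γ_nm is informed by only a
  handful of binary responses, so the centered pair (γ | Σ) / (Σ | γ) moves
  the RA testlet variance in small steps. An additional ancillarity-style
  Metropolis move proposes γ*_m = s·γ_m jointly with σ²_γ → s²σ²_γ and
  σ_γλ → s·σ_γλ (s log-normal). This map leaves the per-person Gaussian
  layer invariant, so the acceptance ratio reduces to the RA likelihood
  ratio, the inverse-Wishart prior ratio and the Jacobian s³, and the
  variance can traverse its posterior in one step. The move changes mixing
  only, not the target; its per-testlet step size adapts like the other
  blocks. The (γ, Σ) layer's correctness is cross-checked in the test suite
  against grid integration of the per-person conditional, and the whole
  layer was validated during development against an independent
  Gauss–Hermite marginal-likelihood estimator.

Initialisation: parameters are drawn from their priors (truncated where
applicable); α starts from marginal item scores (mastery when a person's
mean score on the items requiring the attribute exceeds the grand mean);
the item and testlet covariance matrices start at their prior scale
matrices rather than raw inverse-Wishart prior draws, because draws at
df = p have no finite mean and can place a chain absurdly far from any
mass. Chains are seeded deterministically from the run seed; identical
seeds give bit-identical chains.

Under `model="jrt"` all γ, λ are clamped to zero and the testlet covariance
updates are skipped. Under `prior_only=True` every data-likelihood term is
dropped, so the sampler targets the joint prior; the test suite uses this
to validate the prior implementation (truncations, gamma and
inverse-Wishart layers) by moment-matching.

Posterior summaries: posterior means and central 95% intervals for
continuous parameters; each α_nk is reported as its marginal posterior mode
(mastery frequency > 0.5 → 1), with exact ties broken toward 0. Marginal
(per-attribute) rather than joint-pattern modes are used so that the
estimate matches the granularity of attribute-level classification rates.

Convergence is monitored with the Brooks–Gelman potential scale reduction
factor (corrected form). Note the estimator's small-sample behaviour: two
literally identical chains give √((n−1)/n), i.e. 0.9995 at n = 1000, not
exactly 1. A result flag (never an error) marks runs whose monitored PSRF
exceeds the configured threshold (default 1.05).

## Fit indices and predictive checking

The deviance is conditional on all latent variables, matching what a Gibbs
sampler monitors. AIC/BIC penalise the plug-in deviance at the posterior
point estimates; the free-parameter count convention is 4 per item + 2 per
attribute + 2 (person factors) + 3 (item means) + 6 (item covariance) + 3
per testlet, and is overridable because published counts for comparable
analyses do not follow a single recoverable convention. DIC is the
conditional DIC D̄ + pD, pD = D̄ − D(point estimates), with α plugged in
at its marginal mode. Marginal (integrated) versions are out of scope.

PPMC draws a replicated dataset per retained draw conditional on that
draw's person and testlet latents — the same conditioning as the
discrepancies — and reports the proportion of draws where the replicated
discrepancy is at least the observed one. RA uses the sum of squared
Pearson residuals, RT the sum of squared standardized errors of log time.
Values near 0.5 indicate adequate fit; the RA and RT channels are checked
separately because omnibus absolute-fit statistics for joint models remain
unsettled.

## Simulator and what it does (not) emulate

The default generating design: 1,000 persons, 30 items, 5 attributes;
items 11–30 evenly split into 4 testlets; Σ_testlet = [[0.50, −0.25],
[−0.25, 0.50]] for every testlet (moderate paired effects, cross
correlation −0.5); (β, δ, ξ) ~ N₃((−2.197, 4.394, 4.000), Σ) with
variances (1, 1, 0.25) and correlations ρ_βδ = −0.8, ρ_βξ = −0.5,
ρ_δξ = 0.3; ω ~ N(2, 0.25) truncated positive (a precision-root must be
positive; the truncation is astronomically rare and implemented by
resampling); Σ_person from variances (1, 0.25) with ρ_θτ = −0.5; ν_k = 1.5
and κ = (−1, −0.5, 0, 0.5, 1). The default Q-matrix is built
programmatically: items 1–10 single attributes cycling 1..5 twice, items
11–20 attribute pairs, items 21–30 attribute triples in a balanced cycle —
every attribute loads on 12 items and is anchored by single-attribute
items, keeping all five columns identifiable.

A hierarchical seed split (persons / items / testlets / observations) makes
every stage independently reproducible from one integer seed.

The simulator emulates complete-case, single-group, unidimensional-speed
data with stationary item parameters. It does not emulate missingness,
within-person speed-accuracy trade-offs, multidimensional latent speed,
multi-group structure, or items belonging to several testlets. Passing
recovery tests therefore demonstrates internal consistency of model and
sampler under the stated generating conditions, not robustness to those
real-data complications.

## Recovery harness and problem sizes

`run_recovery_study` replicates simulate → fit → score. Summaries: MA_Bias
is the mean over units of |mean over replications of (est − true)| (mean
absolute bias, absolute value taken after averaging over replications);
M_RMSE the mean over units of per-unit RMSE; the truth–estimate correlation
pools all units and replications of a parameter class into one Pearson
coefficient. ACCR/PCCR pool persons and replications. Covariance and mean
vector parameters, whose truths are fixed by the design, report plain bias
and RMSE over replications. Sampler failures are counted and reported,
never silently dropped.

The package's default study profile is R = 5 replications with 2 chains ×
3,000 iterations (burn-in 1,500, thinning 5) at the full N = 1,000 design —
chosen as the smallest study that stabilises the headline recovery metrics
while remaining desk-scale; a production profile (R = 30, 2 × 10,000
iterations) uses the same code path via `McmcConfig` defaults.

## Numerical notes

* Bernoulli log-mass uses the softplus form y·x − log(1+eˣ) with a
  clipped-exponential softplus (exact to beyond double rounding for
  |x| ≤ 30, linear beyond).
* Success probabilities inside PPMC are clipped to [1e−12, 1−1e−12] before
  forming Pearson residuals.
* The ψ and conditional-variance expressions guard against degenerate
  testlet covariances with a 1e−10 floor.
* A non-finite deviance during sampling aborts the run with a diagnostic
  message (parameter ranges at the failing iteration); convergence-flag
  issues are warnings, not errors.
* Times are stored on disk in seconds and logged on ingest; log/exp
  round-trips are exact to ≤1 ulp with shortest-repr CSV formatting, and
  truth records serialise losslessly through JSON.

## Known limitations

* The sampler is single-machine and dense; very large testlet counts imply
  many 2×2 inverse-Wishart updates per iteration.
* Conditional (not marginal) deviance makes AIC/BIC/DIC comparisons
  meaningful between the two bundled models but not against
  marginal-likelihood analyses.
* The exact free-parameter count for information criteria is convention-
  dependent; use the override when comparing against other software.
* Attribute estimates use marginal modes; joint-pattern modes can differ
  for strongly correlated attributes.
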