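# jtdina

Joint testlet-DINA modelling of response accuracy (RA) and response times
(RT) with **paired local item dependence**.

Computer-based tests routinely record how long each examinee spends on each
item alongside whether they answered it correctly. Joint models exploit both
channels, but items grouped around a common stimulus (a *testlet*) violate
the usual conditional-independence assumptions twice over: the shared
stimulus induces residual dependence among the correctness responses *and*
among the response times of its items, and the two dependencies arrive in
pairs. `jtdina` implements a cognitive-diagnosis model that absorbs both
with correlated person-by-testlet random effects, together with a
full-Bayesian MCMC sampler, a simulator with known generating truth, model
comparison tooling and a parameter-recovery harness. Its audience is
psychometricians and methodologists working on diagnostic measurement with
response times.

## The model

For person $n$ and item $i$, with binary attribute profile
$\boldsymbol\alpha_n \in \{0,1\}^K$ and Q-matrix entry $q_{ik}$:

$$\mathrm{logit}\,P(Y_{ni}=1) = \beta_i + \delta_i \prod_{k=1}^K \alpha_{nk}^{q_{ik}} + \sum_{m=1}^M u_{im}\gamma_{nm}$$

$$\log T_{ni} \sim N\!\Big(\xi_i - \tau_n - \sum_{m=1}^M u_{im}\lambda_{nm},\ \omega_i^{-2}\Big)$$

The conjunctive (DINA) product is 1 only when every attribute the item
requires is mastered; $\beta_i$ and $\delta_i$ set the guessing
($\mathrm{expit}\,\beta_i$) and slip ($1-\mathrm{expit}(\beta_i+\delta_i)$)
probabilities; $\xi_i$ is time intensity, $\tau_n$ latent speed and
$\omega_i$ time-kurtosis. The U-matrix entry $u_{im}$ flags testlet
membership, and the paired effects $(\gamma_{nm}, \lambda_{nm})$ follow a
bivariate normal with testlet-specific covariance $\Sigma_{\mathrm{testlet},m}$.
Above the measurement layer, mastery follows a higher-order logistic
structure $\mathrm{logit}\,P(\alpha_{nk}=1) = \nu_k\theta_n - \kappa_k$;
$(\theta_n, \tau_n)$ are bivariate normal with unit ability variance
(parameterised through Cholesky factors $\varphi, \psi$), and
$(\beta_i,\delta_i,\xi_i)$ are trivariate normal with mean
$\boldsymbol\mu_{\mathrm{item}}$ and covariance $\Sigma_{\mathrm{item}}$.
Forcing every testlet effect to zero recovers the baseline joint
responses-and-times DINA model (**JRT-DINA**).

Estimation is Metropolis-within-Gibbs with exact Bernoulli full
conditionals for the $\alpha_{nk}$, conjugate updates for the RT layer and
every covariance block (inverse-Wishart), and adaptive random-walk steps
for the logistic blocks. Model comparison offers −2LL/AIC/BIC, a
conditional DIC and posterior predictive checking with separate RA
(squared Pearson residual) and RT (squared standardized error) discrepancy
measures.

## Worked example

```python
import numpy as np
from jtdina import default_design, simulate_dataset, fit, McmcConfig, fit_indices

design = default_design(seed=1)           # N=1000, I=30, K=5, M=4 testlets
data, truth = simulate_dataset(design)

cfg = McmcConfig(n_chains=2, n_iterations=3000, burn_in=1500, thin=5, seed=3)
result = fit(data, cfg)

est = result.point_estimates()
print("beta correlation:", np.corrcoef(est["beta"], truth.items.beta)[0, 1])
print("tau correlation: ", np.corrcoef(est["tau"], truth.persons.tau)[0, 1])
print("Sigma_testlet[0]:\n", est["Sigma_testlet"][0].round(3))
```

Output from this exact script:

```
beta correlation: 0.9867755538978528
tau correlation:  0.962391603273316
Sigma_testlet[0]:
 [[ 0.496 -0.244]
 [-0.244  0.513]]
```

The intercepts and latent speeds track their generating values closely, and
the first testlet's estimated effect covariance sits near the generating
$[[0.5, -0.25], [-0.25, 0.5]]$. Fitting the same data with
`McmcConfig(model="jrt")` and comparing `fit_indices` for the two fits
shows AIC, BIC and DIC all preferring the testlet model when paired
dependence is present.

A command-line surface wraps the same pipeline:

```bash
jtdina simulate --seed 1 --out sim/
jtdina fit --y sim/Y.csv --t sim/T.csv --q sim/Q.csv --u sim/U.csv --out fit/
jtdina compare --y sim/Y.csv --t sim/T.csv --q sim/Q.csv --u sim/U.csv --out cmp/
jtdina recover --R 5 --profile scaled --out rec/
```

Every command writes a reproducibility manifest; outputs regenerate
bit-identically from the manifest's seed and options.

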