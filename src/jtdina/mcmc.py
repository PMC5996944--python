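"""Metropolis-within-Gibbs estimation of the joint testlet-DINA model.

Blocks with tractable full conditionals are sampled exactly:

* attribute indicators ``alpha_nk`` — exact Bernoulli full conditional
  combining the higher-order prior with the RA likelihood ratio;
* latent speed ``tau_n``, time intensity ``xi_i`` and RT testlet effect
  ``lambda_nm`` — conjugate normal updates given the lognormal RT layer;
* RT precision ``omega_i**2`` — conjugate gamma;
* ``Sigma_item`` and every ``Sigma_testlet,m`` — conjugate inverse-Wishart;
* item mean vector ``mu_item`` — componentwise normal (truncated for
  ``mu_delta``) and person factor ``phi`` — conjugate normal.

Logit-scale blocks (``beta_i``, ``delta_i``, ``theta_n``, ``gamma_nm``,
``nu_k``, ``kappa_k``) and the positive scale factor ``psi`` use adaptive
random-walk Metropolis steps, tuned toward 20-50% acceptance during burn-in
and frozen afterwards. Under ``model="jrt"`` all testlet effects are clamped
to zero and the testlet covariance layer is skipped, giving the baseline
model that ignores paired local item dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .model import (
    CovarianceLayers,
    Dataset,
    ItemParameters,
    PersonState,
    StructuralParameters,
    TestletEffects,
    mastery_matrix,
)

__all__ = [
    "McmcConfig",
    "PriorSpec",
    "PosteriorResult",
    "fit",
    "alpha_conditional_probability",
    "psrf",
    "summarize",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + e^x), clipped-exp formulation (much faster than logaddexp)."""
    out = np.clip(x, -30.0, 30.0)
    np.exp(out, out=out)
    np.log1p(out, out=out)
    return np.where(x > 30.0, x, out)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler run configuration.

    Defaults mirror a production run (2 chains of 10,000 iterations, half
    burn-in, thinning 5); the recovery harness uses a shorter profile.
    """

    n_chains: int = 2
    n_iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    model: str = "joint_testlet"
    psrf_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.model not in ("joint_testlet", "jrt"):
            raise ValueError(f"unknown model flag {self.model!r}")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class PriorSpec:
    """Priors and hyperpriors of the full-Bayesian specification.

    Item vectors (beta, delta, xi) are trivariate normal given
    (mu_item, Sigma_item); the RT residual variance omega**-2 is
    InvGamma(1, 1), i.e. the precision omega**2 is Gamma(1, 1). Hyperpriors:
    mu_beta ~ N(-2.197, 2), mu_delta ~ N(4.394, 2) truncated positive,
    mu_xi ~ N(3, 2), Sigma_item ~ InvWishart(I3, 3). The person layer uses
    phi ~ N(0, 1) and psi ~ Gamma(1, 1) on the Cholesky factors of
    Sigma_person. Structural parameters: kappa_k ~ N(0, 4) and
    nu_k ~ N(0, 4) truncated positive. Each Sigma_testlet,m ~ InvWishart(I2, 2).
    Inverse-Wishart convention: density proportional to
    |S|^{-(df+p+1)/2} exp(-tr(scale @ inv(S))/2). Normal second arguments are
    variances.
    """

    mu_beta_mean: float = -2.197
    mu_beta_var: float = 2.0
    mu_delta_mean: float = 4.394
    mu_delta_var: float = 2.0
    mu_xi_mean: float = 3.0
    mu_xi_var: float = 2.0
    sigma_item_df: float = 3.0
    omega_prec_shape: float = 1.0
    omega_prec_rate: float = 1.0
    phi_mean: float = 0.0
    phi_var: float = 1.0
    psi_shape: float = 1.0
    psi_rate: float = 1.0
    kappa_var: float = 4.0
    nu_var: float = 4.0
    sigma_testlet_df: float = 2.0


def _invwishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition.

    Same convention as scipy.stats.invwishart (density proportional to
    |S|^{-(df+p+1)/2} exp(-tr(scale @ inv(S)) / 2)); hand-rolled to avoid
    per-call overhead in the sampler's inner loop.
    """
    p = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
    idx = np.tril_indices(p, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    W = L @ A
    W = W @ W.T  # Wishart(df, inv(scale))
    sigma = np.linalg.inv(W)
    return 0.5 * (sigma + sigma.T)


def _truncnorm_positive(mean, sd, rng):
    """Inverse-CDF draw from N(mean, sd^2) restricted to the positive half-line."""
    mean = np.asarray(mean, dtype=float)
    lo = ndtr(-mean / sd)  # P(Z <= -mean/sd), mass below zero
    u = lo + (1.0 - lo) * rng.random(mean.shape if mean.shape else None)
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return mean + sd * ndtri(u)


def alpha_conditional_probability(
    Y: np.ndarray,
    beta: np.ndarray,
    delta: np.ndarray,
    testlet_contrib: np.ndarray,
    Q: np.ndarray,
    alpha: np.ndarray,
    theta: np.ndarray,
    nu: np.ndarray,
    kappa: np.ndarray,
    k: int,
) -> np.ndarray:
    """Exact full-conditional mastery probability P(alpha_nk = 1 | rest).

    Combines the higher-order prior odds with the RA likelihood ratio of the
    two mastery states over the items requiring attribute ``k`` (all other
    attributes held fixed). If no item loads on ``k``, the posterior equals
    the prior. No Metropolis correction is needed.
    """
    items_k = np.flatnonzero(Q[:, k] == 1)
    prior_logit = nu[k] * theta - kappa[k]
    if items_k.size == 0:
        return expit(prior_logit)
    Qk = Q[items_k].copy()
    Qk[:, k] = 0
    eta_other = (alpha @ Qk.T == Qk.sum(axis=1)[None, :]).astype(float)
    x0 = beta[items_k][None, :] + testlet_contrib[:, items_k]
    x1 = x0 + delta[items_k][None, :] * eta_other
    y = Y[:, items_k].astype(float)
    ll1 = (y * x1 - np.logaddexp(0.0, x1)).sum(axis=1)
    ll0 = (y * x0 - np.logaddexp(0.0, x0)).sum(axis=1)
    return expit(prior_logit + ll1 - ll0)


@dataclass
class PosteriorResult:
    """Retained draws, summaries and diagnostics from one fitted model.

    ``draws`` maps parameter-block names to arrays of shape
    ``(n_chains, n_draws, *block_shape)``; ``deviance`` holds -2 log
    likelihood per retained draw for DIC.
    """

    draws: dict[str, np.ndarray]
    deviance: np.ndarray  # (n_chains, n_draws)
    config: McmcConfig
    priors: PriorSpec
    acceptance: dict[str, float] = field(default_factory=dict)
    psrf_flag: bool = False  # True if any monitored PSRF exceeded threshold

    @property
    def n_retained(self) -> int:
        return self.deviance.shape[0] * self.deviance.shape[1]

    def _flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def point_estimates(self) -> dict[str, np.ndarray]:
        """Posterior means for continuous blocks; marginal mode for alpha."""
        out = {}
        for name, d in self.draws.items():
            flat = d.reshape(-1, *d.shape[2:])
            if name == "alpha":
                out[name] = (flat.mean(axis=0) > 0.5).astype(np.int8)
            else:
                out[name] = flat.mean(axis=0)
        return out

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        flat = self._flat(name)
        a = 100 * (1 - level) / 2
        return np.percentile(flat, a, axis=0), np.percentile(flat, 100 - a, axis=0)

    def psrf(self, names: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
        """Brooks-Gelman potential scale reduction factor per parameter."""
        if names is None:
            names = tuple(n for n in self.draws if n != "alpha")
        out = {}
        for name in names:
            d = self.draws[name]
            flat = d.reshape(d.shape[0], d.shape[1], -1)
            out[name] = np.array([psrf(flat[:, :, j]) for j in range(flat.shape[2])])
        return out

    def point_state(self, data: Dataset):
        """Plug-in latent state at posterior summaries (for conditional DIC)."""
        est = self.point_estimates()
        items = ItemParameters(est["beta"], est["delta"], est["xi"], est["omega"])
        persons = PersonState(est["theta"], est["tau"], est["alpha"])
        M = data.U.n_testlets
        if self.config.model == "jrt" or M == 0:
            testlets = TestletEffects.zeros(data.n_persons, M)
        else:
            testlets = TestletEffects(est["gamma"], est["lam"])
        return items, persons, testlets


def psrf(chains: np.ndarray) -> float:
    """Brooks-Gelman corrected potential scale reduction factor.

    ``chains`` has shape (m, n): m >= 2 chains of n >= 10 retained draws.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("psrf needs >=2 chains of draws")
    m, n = chains.shape
    if n < 10:
        raise ValueError("psrf needs >=10 retained draws per chain")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0
    sigma_hat2 = (n - 1) / n * W + B_over_n
    r2 = (m + 1) / m * sigma_hat2 / W - (n - 1) / (m * n)
    return float(np.sqrt(max(r2, 0.0)))


def summarize(result: PosteriorResult, names: tuple[str, ...] | None = None):
    """Posterior mean, SD, central 95% interval and PSRF per scalar parameter.

    Attribute indicators are reported as marginal mastery frequencies with
    their modal (majority-rule, ties to 0) estimate.
    """
    import pandas as pd

    if names is None:
        names = tuple(n for n in result.draws if n not in ("alpha", "theta", "tau",
                                                           "gamma", "lam"))
    rows = []
    for name in names:
        d = result.draws[name]
        flat = d.reshape(d.shape[0], d.shape[1], -1)
        pooled = flat.reshape(-1, flat.shape[2])
        lo = np.percentile(pooled, 2.5, axis=0)
        hi = np.percentile(pooled, 97.5, axis=0)
        for j in range(flat.shape[2]):
            label = name if flat.shape[2] == 1 else f"{name}[{j}]"
            rows.append({
                "parameter": label,
                "mean": pooled[:, j].mean(),
                "sd": pooled[:, j].std(ddof=1),
                "q2.5": lo[j],
                "q97.5": hi[j],
                "psrf": psrf(flat[:, :, j]),
            })
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _Adapt:
    """Per-coordinate random-walk step with burn-in tuning to ~35% acceptance."""

    def __init__(self, shape, init=0.5):
        self.step = np.full(shape, float(init))
        self.accepted = np.zeros(shape)
        self.window = 0

    def record(self, acc):
        self.accepted += acc
        self.window += 1

    def tune(self):
        if self.window == 0:
            return
        rate = self.accepted / self.window
        self.step *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))
        np.clip(self.step, 1e-3, 10.0, out=self.step)
        self.accepted[...] = 0.0
        self.window = 0


class _ChainSampler:
    def __init__(self, data: Dataset, config: McmcConfig, priors: PriorSpec,
                 seed: int, prior_only: bool = False):
        self.data = data
        self.config = config
        self.priors = priors
        self.prior_only = prior_only
        self.rng = np.random.default_rng(seed)
        self.joint = config.model == "joint_testlet" and data.U.n_testlets > 0

        self.Y = data.Y.astype(float)
        self.logT = data.logT
        self.Q = data.Q.entries.astype(np.int64)
        self.Uf = data.U.entries.astype(float)
        self.N, self.I = data.Y.shape
        self.K = data.Q.n_attributes
        self.M = data.U.n_testlets
        self.items_in_testlet = [np.flatnonzero(data.U.entries[:, m]) for m in range(self.M)]
        self.items_with_attr = [np.flatnonzero(self.Q[:, k]) for k in range(self.K)]
        self.Qf = self.Q.astype(float)
        self.Q_need = self.Q.sum(axis=1).astype(float)
        # Q with column k zeroed, for "other attributes" mastery
        self._Q_other = []
        for k in range(self.K):
            qk = self.Q[self.items_with_attr[k]].copy()
            qk[:, k] = 0
            self._Q_other.append((qk.astype(float), qk.sum(axis=1).astype(float)))

        self._init_state()
        self._init_steps()

    # -- initialisation ----------------------------------------------------

    def _init_state(self):
        rng, pr = self.rng, self.priors
        self.mu_item = np.array([
            rng.normal(pr.mu_beta_mean, np.sqrt(pr.mu_beta_var)),
            _truncnorm_positive(pr.mu_delta_mean, np.sqrt(pr.mu_delta_var), rng),
            rng.normal(pr.mu_xi_mean, np.sqrt(pr.mu_xi_var)),
        ])
        # prior scale matrices as covariance starting points: InvWishart prior
        # draws at df=p have no finite mean and can start chains absurdly far out
        self.Sigma_item = np.eye(3)
        self._P_item = np.linalg.inv(self.Sigma_item)
        psi_vec = rng.multivariate_normal(self.mu_item, self.Sigma_item, size=self.I)
        self.beta = psi_vec[:, 0]
        self.delta = psi_vec[:, 1]
        self.xi = psi_vec[:, 2]
        self.omega_prec = rng.gamma(pr.omega_prec_shape, 1.0 / pr.omega_prec_rate,
                                    size=self.I)
        self.omega_prec = np.clip(self.omega_prec, 1e-3, None)
        self.phi = rng.normal(pr.phi_mean, np.sqrt(pr.phi_var))
        self.psi = max(rng.gamma(pr.psi_shape, 1.0 / pr.psi_rate), 1e-2)
        self.nu = np.asarray(_truncnorm_positive(
            np.zeros(self.K), np.sqrt(self.priors.nu_var), rng))
        self.kappa = rng.normal(0.0, np.sqrt(self.priors.kappa_var), size=self.K)
        sp = self.Sigma_person
        z = rng.standard_normal((self.N, 2)) @ np.linalg.cholesky(sp).T
        self.theta, self.tau = z[:, 0], z[:, 1]

        # alpha from marginal item scores: mastery if the person scores above
        # the grand mean on the items requiring the attribute
        alpha = np.zeros((self.N, self.K), dtype=np.int8)
        for k in range(self.K):
            cols = self.items_with_attr[k]
            score = self.Y[:, cols].mean(axis=1)
            alpha[:, k] = (score >= score.mean()).astype(np.int8)
        self.alpha = alpha

        self.Sigma_testlet = np.broadcast_to(np.eye(2), (self.M, 2, 2)).copy()
        if self.joint:
            self.gamma = np.zeros((self.N, self.M))
            self.lam = np.zeros((self.N, self.M))
            for m in range(self.M):
                g = rng.multivariate_normal(np.zeros(2), self.Sigma_testlet[m],
                                            size=self.N)
                self.gamma[:, m], self.lam[:, m] = g[:, 0], g[:, 1]
        else:
            self.gamma = np.zeros((self.N, self.M))
            self.lam = np.zeros((self.N, self.M))

        self.eta = mastery_matrix(self.alpha, self.Q).astype(float)
        self.tc = self.gamma @ self.Uf.T  # (N, I) RA testlet contribution
        self.lc = self.lam @ self.Uf.T

    def _init_steps(self):
        self.st_theta = _Adapt(self.N, 1.0)
        self.st_beta = _Adapt(self.I, 0.3)
        self.st_delta = _Adapt(self.I, 0.3)
        self.st_shear = _Adapt(self.I, 0.5)
        self.st_tloc = _Adapt((), 0.05)
        self.st_gamma = _Adapt((self.N, self.M), 0.8) if self.M else None
        self.st_tscale = _Adapt(self.M, 0.08) if self.M else None
        self.st_nu = _Adapt(self.K, 0.3)
        self.st_kappa = _Adapt(self.K, 0.3)
        self.st_psi = _Adapt((), 0.3)

    # -- helpers -----------------------------------------------------------

    @property
    def Sigma_person(self) -> np.ndarray:
        return np.array([
            [1.0, self.phi],
            [self.phi, self.phi ** 2 + self.psi ** 2],
        ])

    def _bern(self, y, x):
        return y * x - _softplus(x)

    # -- Gibbs blocks ------------------------------------------------------

    def update_alpha(self):
        # The RA log-likelihood contrast for flipping alpha_nk only involves
        # items requiring k, and only through persons mastering the item's
        # *other* attributes; there the logit moves from beta+tc to
        # beta+delta+tc regardless of k. Precompute both softplus fields once.
        alpha_f = self.alpha.astype(float)
        if not self.prior_only:
            x0 = self.beta[None, :] + self.tc
            contrast = (self.Y * self.delta[None, :] - _softplus(x0 + self.delta[None, :])
                        + _softplus(x0))
        for k in range(self.K):
            items_k = self.items_with_attr[k]
            prior_logit = self.nu[k] * self.theta - self.kappa[k]
            if self.prior_only or items_k.size == 0:
                p = expit(prior_logit)
            else:
                qk, need = self._Q_other[k]
                eta_other = (alpha_f @ qk.T == need[None, :])
                d = (contrast[:, items_k] * eta_other).sum(axis=1)
                p = expit(prior_logit + d)
            new = (self.rng.random(self.N) < p)
            self.alpha[:, k] = new
            alpha_f[:, k] = new
        self.eta = (alpha_f @ self.Qf.T == self.Q_need[None, :]).astype(float)

    def update_theta(self, adapting):
        s2 = self.phi ** 2 + self.psi ** 2
        cond_mean = (self.phi / s2) * self.tau
        cond_var = 1.0 - self.phi ** 2 / s2
        x_cur = self.theta[:, None] * self.nu[None, :] - self.kappa[None, :]
        ll_cur = self._bern(self.alpha, x_cur).sum(axis=1)
        lp_cur = -0.5 * (self.theta - cond_mean) ** 2 / cond_var + ll_cur
        prop = self.theta + self.st_theta.step * self.rng.standard_normal(self.N)
        x_p = prop[:, None] * self.nu[None, :] - self.kappa[None, :]
        ll_p = self._bern(self.alpha, x_p).sum(axis=1)
        lp_p = -0.5 * (prop - cond_mean) ** 2 / cond_var + ll_p
        acc = np.log(self.rng.random(self.N)) < lp_p - lp_cur
        self.theta = np.where(acc, prop, self.theta)
        if adapting:
            self.st_theta.record(acc)

    def update_tau(self):
        prior_mean = self.phi * self.theta
        prior_prec = 1.0 / self.psi ** 2
        if self.prior_only:
            post_prec = np.full(self.N, prior_prec)
            post_mean = prior_mean
        else:
            w = self.omega_prec  # omega^2 per item
            r = self.xi[None, :] - self.lc - self.logT  # tau "observations"
            post_prec = prior_prec + w.sum()
            post_mean = (prior_mean * prior_prec + r @ w) / post_prec
        self.tau = post_mean + self.rng.standard_normal(self.N) / np.sqrt(post_prec)

    def update_gamma(self, adapting):
        if not self.joint:
            return
        for m in range(self.M):
            S = self.Sigma_testlet[m]
            c_mean = (S[0, 1] / S[1, 1]) * self.lam[:, m]
            c_var = max(S[0, 0] - S[0, 1] ** 2 / S[1, 1], 1e-10)
            items_m = self.items_in_testlet[m]
            g = self.gamma[:, m]
            base = (self.beta[items_m][None, :]
                    + self.delta[items_m][None, :] * self.eta[:, items_m]
                    + self.tc[:, items_m] - g[:, None])
            y = self.Y[:, items_m]
            prop = g + self.st_gamma.step[:, m] * self.rng.standard_normal(self.N)
            if self.prior_only:
                ll_cur = ll_p = 0.0
            else:
                ll_cur = self._bern(y, base + g[:, None]).sum(axis=1)
                ll_p = self._bern(y, base + prop[:, None]).sum(axis=1)
            lp_cur = -0.5 * (g - c_mean) ** 2 / c_var + ll_cur
            lp_p = -0.5 * (prop - c_mean) ** 2 / c_var + ll_p
            acc = np.log(self.rng.random(self.N)) < lp_p - lp_cur
            new = np.where(acc, prop, g)
            self.tc[:, items_m] += (new - g)[:, None]
            self.gamma[:, m] = new
            if adapting:
                self.st_gamma.accepted[:, m] += acc
        if adapting and self.M:
            self.st_gamma.window += 1

    def update_lambda(self):
        if not self.joint:
            return
        for m in range(self.M):
            S = self.Sigma_testlet[m]
            c_mean = (S[0, 1] / S[0, 0]) * self.gamma[:, m]
            c_var = max(S[1, 1] - S[0, 1] ** 2 / S[0, 0], 1e-10)
            items_m = self.items_in_testlet[m]
            lam_m = self.lam[:, m]
            if self.prior_only:
                post_prec = np.full(self.N, 1.0 / c_var)
                post_mean = c_mean
            else:
                w = self.omega_prec[items_m]
                lc_other = self.lc[:, items_m] - lam_m[:, None]
                obs = (self.xi[items_m][None, :] - self.tau[:, None]
                       - lc_other - self.logT[:, items_m])
                post_prec = 1.0 / c_var + w.sum()
                post_mean = (c_mean / c_var + obs @ w) / post_prec
            new = post_mean + self.rng.standard_normal(self.N) / np.sqrt(post_prec)
            self.lc[:, items_m] += (new - lam_m)[:, None]
            self.lam[:, m] = new

    def _item_prior_conditionals(self, j):
        """Conditional prior N(mean_i, var) of item coordinate j given the others."""
        P = self._P_item
        psi_mat = np.column_stack([self.beta, self.delta, self.xi])
        dev = psi_mat - self.mu_item[None, :]
        others = [l for l in range(3) if l != j]
        mean = self.mu_item[j] - (dev[:, others] @ P[j, others]) / P[j, j]
        return mean, 1.0 / P[j, j]

    def update_beta(self, adapting):
        m0, v0 = self._item_prior_conditionals(0)
        prop = self.beta + self.st_beta.step * self.rng.standard_normal(self.I)
        if self.prior_only:
            dll = np.zeros(self.I)
        else:
            x_cur = self.beta[None, :] + self.delta[None, :] * self.eta + self.tc
            x_p = x_cur + (prop - self.beta)[None, :]
            dll = (self._bern(self.Y, x_p) - self._bern(self.Y, x_cur)).sum(axis=0)
        dlp = dll - 0.5 * ((prop - m0) ** 2 - (self.beta - m0) ** 2) / v0
        acc = np.log(self.rng.random(self.I)) < dlp
        self.beta = np.where(acc, prop, self.beta)
        if adapting:
            self.st_beta.record(acc)

    def update_delta(self, adapting):
        m0, v0 = self._item_prior_conditionals(1)
        prop = self.delta + self.st_delta.step * self.rng.standard_normal(self.I)
        if self.prior_only:
            dll = np.zeros(self.I)
        else:
            x_cur = self.beta[None, :] + self.delta[None, :] * self.eta + self.tc
            x_p = x_cur + ((prop - self.delta)[None, :]) * self.eta
            dll = (self._bern(self.Y, x_p) - self._bern(self.Y, x_cur)).sum(axis=0)
        dlp = dll - 0.5 * ((prop - m0) ** 2 - (self.delta - m0) ** 2) / v0
        acc = np.log(self.rng.random(self.I)) < dlp
        self.delta = np.where(acc, prop, self.delta)
        if adapting:
            self.st_delta.record(acc)

    def update_beta_delta_shear(self, adapting):
        """Ridge move: beta* = beta + e, delta* = delta - e per item.

        beta and delta are strongly anti-correlated (the likelihood pins
        beta + delta for persons mastering the item while beta alone is
        informed only by non-masters), so coordinatewise walks zig-zag along
        the ridge. The shear leaves every eta=1 response term invariant;
        only eta=0 terms and the trivariate prior enter the ratio.
        """
        e = self.st_shear.step * self.rng.standard_normal(self.I)
        if self.prior_only:
            dll = np.zeros(self.I)
        else:
            x_cur = self.beta[None, :] + self.delta[None, :] * self.eta + self.tc
            x_p = x_cur + e[None, :] * (1.0 - self.eta)
            dll = (self._bern(self.Y, x_p) - self._bern(self.Y, x_cur)).sum(axis=0)
        P = self._P_item
        dev = np.column_stack([self.beta, self.delta, self.xi]) - self.mu_item[None, :]
        u = np.array([1.0, -1.0, 0.0])
        Pu = P @ u
        dlp = dll - e * (dev @ Pu) - 0.5 * e ** 2 * (u @ Pu)
        acc = np.log(self.rng.random(self.I)) < dlp
        self.beta = np.where(acc, self.beta + e, self.beta)
        self.delta = np.where(acc, self.delta - e, self.delta)
        if adapting:
            self.st_shear.record(acc)

    def update_xi(self):
        m0, v0 = self._item_prior_conditionals(2)
        if self.prior_only:
            post_prec = np.full(self.I, 1.0 / v0)
            post_mean = m0
        else:
            w = self.omega_prec
            obs = self.logT + self.tau[:, None] + self.lc  # xi "observations"
            post_prec = 1.0 / v0 + self.N * w
            post_mean = (m0 / v0 + w * obs.sum(axis=0)) / post_prec
        self.xi = post_mean + self.rng.standard_normal(self.I) / np.sqrt(post_prec)

    def update_time_location(self, adapting):
        """Global translation move: xi + c, tau + c, mu_xi + c.

        The RT likelihood depends on xi_i - tau_n only, leaving a soft ridge
        in the common location of time intensity and speed that coordinate
        updates cross slowly. The translation leaves the likelihood and the
        xi prior (centred at mu_xi) invariant; only the tau prior (mean
        phi*theta) and the mu_xi hyperprior enter the ratio.
        """
        c = float(self.st_tloc.step * self.rng.standard_normal())
        pr = self.priors
        resid = self.tau - self.phi * self.theta
        dlp = -(2.0 * c * resid.sum() + self.N * c * c) / (2.0 * self.psi ** 2)
        m, v = pr.mu_xi_mean, pr.mu_xi_var
        dlp += -((self.mu_item[2] + c - m) ** 2 - (self.mu_item[2] - m) ** 2) / (2.0 * v)
        acc = np.log(self.rng.random()) < dlp
        if acc:
            self.xi = self.xi + c
            self.tau = self.tau + c
            self.mu_item[2] += c
        if adapting:
            self.st_tloc.record(float(acc))

    def update_omega(self):
        pr = self.priors
        if self.prior_only:
            self.omega_prec = self.rng.gamma(pr.omega_prec_shape,
                                             1.0 / pr.omega_prec_rate, size=self.I)
        else:
            resid = self.logT - (self.xi[None, :] - self.tau[:, None] - self.lc)
            ss = (resid ** 2).sum(axis=0)
            shape = pr.omega_prec_shape + 0.5 * self.N
            rate = pr.omega_prec_rate + 0.5 * ss
            self.omega_prec = self.rng.gamma(shape, 1.0 / rate)
        self.omega_prec = np.clip(self.omega_prec, 1e-8, None)

    def update_mu_item(self):
        pr = self.priors
        P = np.linalg.inv(self.Sigma_item)
        S = np.array([self.beta.sum(), self.delta.sum(), self.xi.sum()])
        prior_mean = np.array([pr.mu_beta_mean, pr.mu_delta_mean, pr.mu_xi_mean])
        prior_var = np.array([pr.mu_beta_var, pr.mu_delta_var, pr.mu_xi_var])
        for j in range(3):
            others = [l for l in range(3) if l != j]
            A = self.I * P[j, j] + 1.0 / prior_var[j]
            b = (P[j, j] * S[j]
                 + sum(P[j, l] * (S[l] - self.I * self.mu_item[l]) for l in others)
                 + prior_mean[j] / prior_var[j])
            mean, sd = b / A, 1.0 / np.sqrt(A)
            if j == 1:  # mu_delta truncated positive
                self.mu_item[j] = float(_truncnorm_positive(mean, sd, self.rng))
            else:
                self.mu_item[j] = mean + sd * self.rng.standard_normal()

    def update_sigma_item(self):
        psi_mat = np.column_stack([self.beta, self.delta, self.xi])
        dev = psi_mat - self.mu_item[None, :]
        scale = np.eye(3) + dev.T @ dev
        df = self.priors.sigma_item_df + self.I
        self.Sigma_item = _invwishart_rvs(df, scale, self.rng)
        self._P_item = np.linalg.inv(self.Sigma_item)

    def update_person_layer(self, adapting):
        pr = self.priors
        # phi | psi, theta, tau: conjugate normal regression tau = phi*theta + psi*z
        prec = 1.0 / pr.phi_var + (self.theta @ self.theta) / self.psi ** 2
        mean = (pr.phi_mean / pr.phi_var
                + (self.theta @ self.tau) / self.psi ** 2) / prec
        self.phi = mean + self.rng.standard_normal() / np.sqrt(prec)
        # psi: random-walk Metropolis on log scale; Gamma(1,1) prior on psi
        sse = float(((self.tau - self.phi * self.theta) ** 2).sum())

        def logp(psi):
            return (- pr.psi_rate * psi + (pr.psi_shape - 1) * np.log(psi)
                    - self.N * np.log(psi) - 0.5 * sse / psi ** 2)

        prop = self.psi * np.exp(self.st_psi.step * self.rng.standard_normal())
        dlp = logp(prop) - logp(self.psi) + np.log(prop) - np.log(self.psi)
        acc = np.log(self.rng.random()) < dlp
        if acc:
            self.psi = float(prop)
        if adapting:
            self.st_psi.record(float(acc))

    def update_structural(self, adapting):
        v0 = self.priors.nu_var
        # nu: random walk, prior N(0, 4) truncated positive
        prop = self.nu + self.st_nu.step * self.rng.standard_normal(self.K)
        x_cur = self.theta[:, None] * self.nu[None, :] - self.kappa[None, :]
        ll_cur = self._bern(self.alpha, x_cur).sum(axis=0)
        x_p = self.theta[:, None] * prop[None, :] - self.kappa[None, :]
        ll_p = self._bern(self.alpha, x_p).sum(axis=0)
        dlp = ll_p - ll_cur - 0.5 * (prop ** 2 - self.nu ** 2) / v0
        acc = (np.log(self.rng.random(self.K)) < dlp) & (prop > 0)
        self.nu = np.where(acc, prop, self.nu)
        if adapting:
            self.st_nu.record(acc)
        # kappa: random walk, prior N(0, 4)
        v0 = self.priors.kappa_var
        prop = self.kappa + self.st_kappa.step * self.rng.standard_normal(self.K)
        x_cur = self.theta[:, None] * self.nu[None, :] - self.kappa[None, :]
        ll_cur = self._bern(self.alpha, x_cur).sum(axis=0)
        x_p = self.theta[:, None] * self.nu[None, :] - prop[None, :]
        ll_p = self._bern(self.alpha, x_p).sum(axis=0)
        dlp = ll_p - ll_cur - 0.5 * (prop ** 2 - self.kappa ** 2) / v0
        acc = np.log(self.rng.random(self.K)) < dlp
        self.kappa = np.where(acc, prop, self.kappa)
        if adapting:
            self.st_kappa.record(acc)

    def update_sigma_testlet(self):
        if not self.joint:
            return
        df0 = self.priors.sigma_testlet_df
        for m in range(self.M):
            g = np.column_stack([self.gamma[:, m], self.lam[:, m]])
            scale = np.eye(2) + g.T @ g
            self.Sigma_testlet[m] = _invwishart_rvs(df0 + self.N, scale, self.rng)

    def update_testlet_scale(self, adapting):
        """Joint rescaling move for (gamma_m, Sigma_testlet_m).

        Each gamma_n is only weakly informed by its few binary responses, so
        the centered Gibbs pair (gamma | Sigma) / (Sigma | gamma) mixes the
        RA variance slowly. Proposing gamma* = s*gamma with the matching
        Sigma rescaling (sigma_g^2 -> s^2 sigma_g^2, sigma_gl -> s*sigma_gl)
        leaves the per-person Gaussian layer invariant, so the acceptance
        ratio is the RA likelihood ratio times the inverse-Wishart prior
        ratio times the Jacobian s^(N+3) / s^N.
        """
        if not self.joint or self.prior_only:
            return
        d = self.priors.sigma_testlet_df
        for m in range(self.M):
            z = self.st_tscale.step[m] * self.rng.standard_normal()
            s = float(np.exp(z))
            items_m = self.items_in_testlet[m]
            g = self.gamma[:, m]
            base = (self.beta[items_m][None, :]
                    + self.delta[items_m][None, :] * self.eta[:, items_m]
                    + self.tc[:, items_m] - g[:, None])
            y = self.Y[:, items_m]
            dll = (self._bern(y, base + (s * g)[:, None])
                   - self._bern(y, base + g[:, None])).sum()
            S = self.Sigma_testlet[m]
            S_new = S.copy()
            S_new[0, 0] *= s * s
            S_new[0, 1] *= s
            S_new[1, 0] *= s
            det, det_new = np.linalg.det(S), np.linalg.det(S_new)
            tr = (S[1, 1] + S[0, 0]) / det          # tr(inv(S)), R = I2
            tr_new = (S_new[1, 1] + S_new[0, 0]) / det_new
            dlp = (dll - 0.5 * (d + 3) * (np.log(det_new) - np.log(det))
                   - 0.5 * (tr_new - tr) + (self.N + 3) * z - self.N * z)
            acc = np.log(self.rng.random()) < dlp
            if acc:
                self.tc[:, items_m] += ((s - 1.0) * g)[:, None]
                self.gamma[:, m] = s * g
                self.Sigma_testlet[m] = S_new
            if adapting:
                self.st_tscale.accepted[m] += float(acc)
        if adapting:
            self.st_tscale.window += 1

    # -- likelihood monitoring --------------------------------------------

    def current_deviance(self) -> float:
        x = self.beta[None, :] + self.delta[None, :] * self.eta + self.tc
        ll_ra = self._bern(self.Y, x).sum()
        mean = self.xi[None, :] - self.tau[:, None] - self.lc
        z2 = self.omega_prec * (self.logT - mean) ** 2
        ll_rt = (0.5 * np.log(self.omega_prec).sum() * self.N
                 - 0.5 * self.N * self.I * _LOG_2PI - 0.5 * z2.sum())
        return float(-2.0 * (ll_ra + ll_rt))

    # -- main loop ---------------------------------------------------------

    def run(self):
        cfg = self.config
        keep = cfg.n_retained_per_chain
        store = {
            "beta": np.empty((keep, self.I)),
            "delta": np.empty((keep, self.I)),
            "xi": np.empty((keep, self.I)),
            "omega": np.empty((keep, self.I)),
            "mu_item": np.empty((keep, 3)),
            "Sigma_item": np.empty((keep, 3, 3)),
            "phi": np.empty((keep, 1)),
            "psi": np.empty((keep, 1)),
            "Sigma_person": np.empty((keep, 2, 2)),
            "nu": np.empty((keep, self.K)),
            "kappa": np.empty((keep, self.K)),
            "theta": np.empty((keep, self.N)),
            "tau": np.empty((keep, self.N)),
            "alpha": np.empty((keep, self.N, self.K), dtype=np.int8),
        }
        if self.joint:
            store["gamma"] = np.empty((keep, self.N, self.M))
            store["lam"] = np.empty((keep, self.N, self.M))
            store["Sigma_testlet"] = np.empty((keep, self.M, 2, 2))
        deviance = np.empty(keep)

        idx = 0
        for it in range(cfg.n_iterations):
            adapting = it < cfg.burn_in
            self.update_alpha()
            self.update_theta(adapting)
            self.update_tau()
            self.update_gamma(adapting)
            self.update_lambda()
            self.update_beta(adapting)
            self.update_delta(adapting)
            self.update_beta_delta_shear(adapting)
            self.update_xi()
            self.update_time_location(adapting)
            self.update_omega()
            self.update_mu_item()
            self.update_sigma_item()
            self.update_person_layer(adapting)
            self.update_structural(adapting)
            self.update_sigma_testlet()
            self.update_testlet_scale(adapting)

            if adapting and (it + 1) % 50 == 0:
                for st in (self.st_theta, self.st_beta, self.st_delta,
                           self.st_shear, self.st_tloc, self.st_nu, self.st_kappa,
                           self.st_psi):
                    st.tune()
                if self.st_gamma is not None:
                    self.st_gamma.tune()
                    self.st_tscale.tune()

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == cfg.thin - 1:
                dev = self.current_deviance() if not self.prior_only else 0.0
                if not np.isfinite(dev):
                    raise FloatingPointError(
                        f"non-finite likelihood at iteration {it}: "
                        f"beta range ({self.beta.min():.3g}, {self.beta.max():.3g}), "
                        f"omega range ({np.sqrt(self.omega_prec).min():.3g}, "
                        f"{np.sqrt(self.omega_prec).max():.3g})"
                    )
                store["beta"][idx] = self.beta
                store["delta"][idx] = self.delta
                store["xi"][idx] = self.xi
                store["omega"][idx] = np.sqrt(self.omega_prec)
                store["mu_item"][idx] = self.mu_item
                store["Sigma_item"][idx] = self.Sigma_item
                store["phi"][idx] = self.phi
                store["psi"][idx] = self.psi
                store["Sigma_person"][idx] = self.Sigma_person
                store["nu"][idx] = self.nu
                store["kappa"][idx] = self.kappa
                store["theta"][idx] = self.theta
                store["tau"][idx] = self.tau
                store["alpha"][idx] = self.alpha
                if self.joint:
                    store["gamma"][idx] = self.gamma
                    store["lam"][idx] = self.lam
                    store["Sigma_testlet"][idx] = self.Sigma_testlet
                deviance[idx] = dev
                idx += 1
        return store, deviance


def fit(
    data: Dataset,
    config: McmcConfig | None = None,
    priors: PriorSpec | None = None,
    prior_only: bool = False,
) -> PosteriorResult:
    """Fit the joint testlet-DINA (or JRT-DINA) model by MCMC.

    Runs ``config.n_chains`` independent chains with seeds derived from
    ``config.seed``; identical seeds give identical chains. With
    ``prior_only=True`` every data-likelihood term is dropped so the sampler
    targets the joint prior (used to validate the prior implementation).
    A warning flag (not an error) is set on the result when any monitored
    PSRF exceeds ``config.psrf_threshold``.
    """
    config = config or McmcConfig()
    priors = priors or PriorSpec()
    chain_stores = []
    chain_devs = []
    for c in range(config.n_chains):
        seed = (config.seed * 100003 + 7919 * c + 1) % (2 ** 31)
        sampler = _ChainSampler(data, config, priors, seed, prior_only=prior_only)
        store, dev = sampler.run()
        chain_stores.append(store)
        chain_devs.append(dev)
    draws = {
        name: np.stack([s[name] for s in chain_stores])
        for name in chain_stores[0]
    }
    deviance = np.stack(chain_devs)
    result = PosteriorResult(draws=draws, deviance=deviance,
                             config=config, priors=priors)
    if config.n_chains >= 2 and config.n_retained_per_chain >= 10:
        monitored = [n for n in ("beta", "delta", "xi", "omega", "mu_item",
                                 "nu", "kappa", "phi", "psi")
                     if n in draws]
        vals = np.concatenate([result.psrf((n,))[n] for n in monitored])
        result.psrf_flag = bool((vals > config.psrf_threshold).any())
    return result
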