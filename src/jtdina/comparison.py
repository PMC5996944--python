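"""Relative fit indices and posterior predictive checking for fitted models.

Deviance is conditional on the latent variables (person, attribute and
testlet draws), matching deviance monitoring in Gibbs samplers; the DIC is
the conditional DIC ``D_bar + pD`` with ``pD = D_bar - D(point estimates)``.
PPMC uses two omnibus discrepancies: the sum of squared Pearson residuals
for the RA model and the sum of squared standardized errors of log time for
the RT model. The PPP value is the proportion of retained draws whose
replicated-data discrepancy meets or exceeds the observed one; values near
0.5 indicate adequate fit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import expit

from .mcmc import PosteriorResult
from .model import (
    Dataset,
    ItemParameters,
    PersonState,
    TestletEffects,
    joint_loglikelihood,
    mastery_matrix,
)

__all__ = [
    "FitIndices",
    "deviance_at",
    "information_criteria",
    "free_parameter_count",
    "dic",
    "ppmc",
    "fit_indices",
]


@dataclass
class FitIndices:
    """-2LL, AIC, BIC, DIC and PPP values for one fitted model."""

    minus2LL: float
    AIC: float
    BIC: float
    DIC: float
    NP: int
    PPP_RA: float
    PPP_RT: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def deviance_at(
    items: ItemParameters,
    persons: PersonState,
    testlets: TestletEffects | None,
    data: Dataset,
    model: str = "joint_testlet",
) -> float:
    """Conditional deviance -2 log L at a complete parameter/latent state."""
    return -2.0 * joint_loglikelihood(data, items, persons, testlets, model=model)


def information_criteria(minus2LL: float, NP: int, N: int) -> tuple[float, float]:
    """AIC = -2LL + 2*NP and BIC = -2LL + NP*log(N)."""
    if NP < 0:
        raise ValueError("NP must be nonnegative")
    if N < 2:
        raise ValueError("N must be >= 2")
    return minus2LL + 2.0 * NP, minus2LL + NP * float(np.log(N))


def free_parameter_count(I: int, K: int, M: int, model: str = "joint_testlet") -> int:
    """Documented free-parameter convention for AIC/BIC.

    4 per item (beta, delta, xi, omega) + 2 per attribute (nu, kappa)
    + 2 person-covariance factors (phi, psi) + 3 item means + 6 free
    item-covariance elements + 3 per testlet covariance (joint model only).
    Other counting conventions exist; pass an explicit NP to override.
    """
    np_count = 4 * I + 2 * K + 2 + 3 + 6
    if model == "joint_testlet":
        np_count += 3 * M
    return np_count


def dic(deviance_draws: np.ndarray, deviance_at_posterior_mean: float) -> float:
    """Conditional DIC: D_bar + pD with pD = D_bar - D(posterior point)."""
    d = np.asarray(deviance_draws, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("need >=2 deviance draws")
    d_bar = d.mean()
    p_d = d_bar - deviance_at_posterior_mean
    return float(d_bar + p_d)


def _discrepancies(draw_state, data, rng):
    """Observed and replicated (D_RA, D_RT) at one retained draw."""
    beta, delta, xi, omega, alpha, tau, tc, lc = draw_state
    eta = mastery_matrix(alpha, data.Q.entries)
    p = expit(beta[None, :] + delta[None, :] * eta + tc)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    y = data.Y.astype(float)
    d_ra_obs = (((y - p) ** 2) / (p * (1 - p))).sum()
    y_rep = (rng.random(p.shape) < p).astype(float)
    d_ra_rep = (((y_rep - p) ** 2) / (p * (1 - p))).sum()
    mean = xi[None, :] - tau[:, None] - lc
    z_obs = omega[None, :] * (data.logT - mean)
    d_rt_obs = (z_obs ** 2).sum()
    t_rep = rng.normal(mean, 1.0 / omega[None, :])
    d_rt_rep = (omega[None, :] * (t_rep - mean)) ** 2
    return d_ra_obs, d_ra_rep, d_rt_obs, d_rt_rep.sum()


def ppmc(
    result: PosteriorResult,
    data: Dataset,
    rng: np.random.Generator,
    max_draws: int | None = 500,
    return_draws: bool = False,
):
    """Posterior predictive p-values (PPP_RA, PPP_RT).

    For each retained draw the replicated dataset is simulated conditional on
    the drawn person and testlet latents (matching the conditioning of the
    discrepancy measures). Returns the proportion of draws with replicated
    discrepancy >= observed, separately for RA and RT. With
    ``return_draws=True`` additionally returns a DataFrame of the per-draw
    observed/replicated discrepancy pairs (scatter data for predictive
    checking plots).
    """
    beta = result._flat("beta")
    delta = result._flat("delta")
    xi = result._flat("xi")
    omega = result._flat("omega")
    alpha = result._flat("alpha")
    tau = result._flat("tau")
    n_draws = beta.shape[0]
    U = data.U.entries.astype(float)
    joint = result.config.model == "joint_testlet" and data.U.n_testlets > 0
    if joint:
        gamma = result._flat("gamma")
        lam = result._flat("lam")
    idx = np.arange(n_draws)
    if max_draws is not None and n_draws > max_draws:
        idx = np.linspace(0, n_draws - 1, max_draws).astype(int)
    rows = np.empty((len(idx), 4))
    for j, d in enumerate(idx):
        tc = gamma[d] @ U.T if joint else np.zeros_like(data.logT)
        lc = lam[d] @ U.T if joint else np.zeros_like(data.logT)
        state = (beta[d], delta[d], xi[d], omega[d], alpha[d], tau[d], tc, lc)
        rows[j] = _discrepancies(state, data, rng)
    ppp_ra = float((rows[:, 1] >= rows[:, 0]).mean())
    ppp_rt = float((rows[:, 3] >= rows[:, 2]).mean())
    if return_draws:
        import pandas as pd

        scatter = pd.DataFrame(rows, columns=["D_RA_observed", "D_RA_replicated",
                                              "D_RT_observed", "D_RT_replicated"])
        scatter.insert(0, "draw", idx)
        return ppp_ra, ppp_rt, scatter
    return ppp_ra, ppp_rt


def fit_indices(
    result: PosteriorResult,
    data: Dataset,
    rng: np.random.Generator | None = None,
    np_count: int | None = None,
    ppp_max_draws: int | None = 500,
) -> FitIndices:
    """Assemble the full fit-index report for one fitted model.

    -2LL is the conditional deviance at the posterior point estimates (alpha
    at its marginal mode); AIC/BIC penalise it with the documented free
    parameter count (or an explicit ``np_count``); DIC uses the monitored
    deviance draws; PPP values come from posterior predictive checking.
    """
    model = result.config.model
    items, persons, testlets = result.point_state(data)
    minus2ll = deviance_at(items, persons, testlets, data, model=model)
    if np_count is None:
        np_count = free_parameter_count(data.n_items, data.Q.n_attributes,
                                        data.U.n_testlets, model)
    aic, bic = information_criteria(minus2ll, np_count, data.n_persons)
    d = dic(result.deviance, minus2ll)
    if rng is None:
        rng = np.random.default_rng(0)
    ppp_ra, ppp_rt = ppmc(result, data, rng, max_draws=ppp_max_draws)
    return FitIndices(minus2LL=float(minus2ll), AIC=float(aic), BIC=float(bic),
                      DIC=float(d), NP=int(np_count),
                      PPP_RA=float(ppp_ra), PPP_RT=float(ppp_rt))
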