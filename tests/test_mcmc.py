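"""Sampler machinery: PSRF, exact conditionals, priors, tiny-fit recovery."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import invwishart

from jtdina.mcmc import (
    McmcConfig,
    PriorSpec,
    _invwishart_rvs,
    _truncnorm_positive,
    alpha_conditional_probability,
    fit,
    psrf,
    summarize,
)
from jtdina.simulate import simulate_dataset

from conftest import tiny_design


# ---------------------------------------------------------------------------
# PSRF
# ---------------------------------------------------------------------------


def test_psrf_identical_chains_is_one():
    chain = np.random.default_rng(0).normal(size=1000)
    r = psrf(np.stack([chain, chain]))
    assert r == pytest.approx(1.0, abs=2e-3)


def test_psrf_iid_chains_converged():
    rng = np.random.default_rng(1)
    chains = rng.normal(size=(2, 1000))
    assert psrf(chains) < 1.05


def test_psrf_disjoint_chains_diverged():
    rng = np.random.default_rng(2)
    chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert psrf(chains) > 1.2


def test_psrf_matches_arviz_on_converged_chains():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(3)
    chains = rng.normal(size=(4, 2000))
    mine = psrf(chains)
    theirs = float(np.asarray(az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"]).ravel()[0])
    assert mine == pytest.approx(theirs, abs=0.01)


def test_psrf_requires_multiple_chains():
    with pytest.raises(ValueError):
        psrf(np.random.default_rng(0).normal(size=(1, 100)))


# ---------------------------------------------------------------------------
# exact attribute full conditional
# ---------------------------------------------------------------------------


def _joint_mass(y, beta, delta, tc, Q, pattern, theta, nu, kappa):
    """Unnormalised joint mass of (alpha pattern, Y) for one person."""
    from jtdina.model import conjunctive_mastery

    mass = 1.0
    for k, a in enumerate(pattern):
        pk = expit(nu[k] * theta - kappa[k])
        mass *= pk if a else 1 - pk
    for i in range(len(beta)):
        eta = conjunctive_mastery(np.array(pattern), Q[i])
        p = expit(beta[i] + delta[i] * eta + tc[i])
        mass *= p if y[i] else 1 - p
    return mass


def test_alpha_conditional_matches_enumeration():
    """K=2 toy: exact conditional equals brute-force over all 4 patterns."""
    Q = np.array([[1, 0], [1, 1]])
    beta = np.array([-1.0, -2.0])
    delta = np.array([3.0, 4.0])
    tc = np.array([[0.3, -0.2]])
    Y = np.array([[1, 0]])
    theta = np.array([0.4])
    nu = np.array([1.5, 1.5])
    kappa = np.array([-0.5, 0.5])
    for fixed_a2 in (0, 1):
        alpha = np.array([[0, fixed_a2]])
        p = alpha_conditional_probability(Y, beta, delta, tc, Q, alpha,
                                          theta, nu, kappa, k=0)
        m1 = _joint_mass(Y[0], beta, delta, tc[0], Q, (1, fixed_a2),
                         theta[0], nu, kappa)
        m0 = _joint_mass(Y[0], beta, delta, tc[0], Q, (0, fixed_a2),
                         theta[0], nu, kappa)
        assert p[0] == pytest.approx(m1 / (m0 + m1), abs=1e-12)


def test_alpha_conditional_reduces_to_prior_without_items():
    Q = np.array([[1, 0], [1, 0]])  # no item loads attribute 2
    # attribute column 2 empty: conditional must equal the higher-order prior
    p = alpha_conditional_probability(
        np.array([[1, 0]]), np.array([-1.0, -1.0]), np.array([2.0, 2.0]),
        np.zeros((1, 2)), Q, np.array([[1, 0]]), np.array([0.7]),
        np.array([1.5, 1.5]), np.array([0.0, 0.2]), k=1)
    assert p[0] == pytest.approx(expit(1.5 * 0.7 - 0.2), abs=1e-12)


def test_alpha_conditional_limit_large_delta():
    """delta -> +inf with an observed success on a mastered-only item forces mastery."""
    Q = np.array([[1]])
    p = alpha_conditional_probability(
        np.array([[1]]), np.array([-15.0]), np.array([30.0]),
        np.zeros((1, 1)), Q, np.array([[0]]), np.array([0.0]),
        np.array([1.5]), np.array([0.0]), k=0)
    assert p[0] > 0.999


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def test_truncnorm_positive_moments():
    rng = np.random.default_rng(0)
    draws = np.array([_truncnorm_positive(-1.0, 1.0, rng) for _ in range(20000)])
    assert (draws > 0).all()
    # closed-form truncated-normal mean: mu + sd * phi(a)/ (1 - Phi(a)), a = -mu/sd
    from scipy.stats import norm

    a = 1.0
    expected = -1.0 + norm.pdf(a) / norm.sf(a)
    assert draws.mean() == pytest.approx(expected, abs=0.02)


def test_invwishart_bartlett_matches_scipy_moments():
    """Hand-rolled Bartlett sampler agrees with scipy.stats.invwishart."""
    rng = np.random.default_rng(5)
    scale = np.array([[2.0, 0.3], [0.3, 1.0]])
    df = 10
    mine = np.mean([_invwishart_rvs(df, scale, rng) for _ in range(4000)], axis=0)
    expected = scale / (df - 2 - 1)  # analytic mean, p=2
    np.testing.assert_allclose(mine, expected, rtol=0.08)
    theirs = invwishart.rvs(df=df, scale=scale, size=4000,
                            random_state=np.random.default_rng(6)).mean(axis=0)
    np.testing.assert_allclose(mine, theirs, rtol=0.08)


# ---------------------------------------------------------------------------
# full conditional cross-checks against independent numerics
# ---------------------------------------------------------------------------


def _grid_moments(logpdf, grid):
    w = np.exp(logpdf - logpdf.max())
    w /= w.sum()
    mean = (grid * w).sum()
    var = ((grid - mean) ** 2 * w).sum()
    return mean, var


def test_tau_conjugate_update_matches_grid_posterior():
    """The conjugate speed update targets the correct full conditional."""
    rng = np.random.default_rng(7)
    phi, psi = -0.25, 0.4
    theta = 0.8
    xi = np.array([3.5, 4.2, 4.8])
    omega = np.array([2.0, 1.5, 2.5])
    logT = np.array([3.9, 4.0, 4.4])
    lc = np.array([0.1, -0.2, 0.0])

    # independent numeric oracle on a grid
    grid = np.linspace(-4, 4, 20001)
    lp = -0.5 * (grid - phi * theta) ** 2 / psi ** 2
    for i in range(3):
        lp = lp - 0.5 * (omega[i] * (logT[i] - (xi[i] - grid - lc[i]))) ** 2
    g_mean, g_var = _grid_moments(lp, grid)

    # analytic update as implemented
    prior_prec = 1 / psi ** 2
    w = omega ** 2
    r = xi - lc - logT
    post_prec = prior_prec + w.sum()
    post_mean = (phi * theta * prior_prec + r @ w) / post_prec
    assert post_mean == pytest.approx(g_mean, abs=1e-6)
    assert 1 / post_prec == pytest.approx(g_var, rel=1e-4)


def test_lambda_conjugate_update_matches_grid_posterior():
    S = np.array([[0.5, -0.25], [-0.25, 0.5]])
    gamma = 0.6
    xi = np.array([4.0, 3.6])
    omega = np.array([2.0, 3.0])
    logT = np.array([3.3, 3.1])
    tau = 0.2
    c_mean = S[0, 1] / S[0, 0] * gamma
    c_var = S[1, 1] - S[0, 1] ** 2 / S[0, 0]

    grid = np.linspace(-5, 5, 20001)
    lp = -0.5 * (grid - c_mean) ** 2 / c_var
    for i in range(2):
        lp = lp - 0.5 * (omega[i] * (logT[i] - (xi[i] - tau - grid))) ** 2
    g_mean, g_var = _grid_moments(lp, grid)

    w = omega ** 2
    obs = xi - tau - logT
    post_prec = 1 / c_var + w.sum()
    post_mean = (c_mean / c_var + obs @ w) / post_prec
    assert post_mean == pytest.approx(g_mean, abs=1e-6)
    assert 1 / post_prec == pytest.approx(g_var, rel=1e-4)


def test_gamma_metropolis_targets_grid_posterior():
    """Long-run gamma draws match grid integration of the full conditional."""
    from jtdina.mcmc import _ChainSampler
    from jtdina.model import mastery_matrix

    data, truth = simulate_dataset(tiny_design(N=30, seed=6))
    cfg = McmcConfig(n_chains=1, n_iterations=100, burn_in=50, thin=5, seed=1)
    s = _ChainSampler(data, cfg, PriorSpec(), 99)
    # freeze everything the gamma conditional conditions on at the truth
    s.beta = truth.items.beta.copy()
    s.delta = truth.items.delta.copy()
    s.alpha = truth.persons.alpha.copy()
    s.eta = mastery_matrix(s.alpha, s.Q).astype(float)
    s.lam = truth.testlets.lam.copy()
    s.Sigma_testlet = np.array([[[0.5, -0.25], [-0.25, 0.5]]])
    s.gamma = truth.testlets.gamma.copy()
    s.tc = s.gamma @ s.Uf.T

    draws = []
    for it in range(6000):
        s.update_gamma(it < 1000)
        if it % 50 == 49 and it < 1000:
            s.st_gamma.tune()
        if it >= 1000:
            draws.append(s.gamma[0, 0])
    draws = np.array(draws)

    S = s.Sigma_testlet[0]
    c_mean = S[0, 1] / S[1, 1] * s.lam[0, 0]
    c_var = S[0, 0] - S[0, 1] ** 2 / S[1, 1]
    grid = np.linspace(-6, 6, 4001)
    lp = -0.5 * (grid - c_mean) ** 2 / c_var
    for i in s.items_in_testlet[0]:
        x = s.beta[i] + s.delta[i] * s.eta[0, i] + grid
        lp = lp + data.Y[0, i] * x - np.log1p(np.exp(x))
    g_mean, g_var = _grid_moments(lp, grid)
    assert draws.mean() == pytest.approx(g_mean, abs=0.08)
    assert draws.var() == pytest.approx(g_var, rel=0.15)


# ---------------------------------------------------------------------------
# fit()
# ---------------------------------------------------------------------------


def test_fit_is_deterministic_given_seed(tiny_sim):
    data, _ = tiny_sim
    cfg = McmcConfig(n_chains=2, n_iterations=120, burn_in=60, thin=2, seed=9)
    r1 = fit(data, cfg)
    r2 = fit(data, cfg)
    np.testing.assert_array_equal(r1.draws["beta"], r2.draws["beta"])
    np.testing.assert_array_equal(r1.draws["alpha"], r2.draws["alpha"])
    np.testing.assert_array_equal(r1.deviance, r2.deviance)


def test_fit_retained_draw_count(tiny_sim):
    data, _ = tiny_sim
    cfg = McmcConfig(n_chains=2, n_iterations=130, burn_in=50, thin=4, seed=1)
    res = fit(data, cfg)
    assert res.draws["beta"].shape == (2, 20, 6)
    assert res.n_retained == 40
    assert set(res.point_estimates()["alpha"].ravel()) <= {0, 1}


def test_tiny_fit_recovers_item_intercepts(short_config, tiny_sim):
    """Self-consistency: posterior concentrates near generating beta."""
    data, truth = tiny_sim
    res = fit(data, short_config)
    flat = res.draws["beta"].reshape(-1, 6)
    z = (flat.mean(axis=0) - truth.items.beta) / flat.std(axis=0, ddof=1)
    assert np.abs(z).max() < 3.0


def test_jrt_fit_has_no_testlet_draws(tiny_sim):
    data, _ = tiny_sim
    cfg = McmcConfig(n_chains=2, n_iterations=120, burn_in=60, thin=2, seed=2,
                     model="jrt")
    res = fit(data, cfg)
    assert "gamma" not in res.draws
    assert "Sigma_testlet" not in res.draws


def test_prior_only_run_reproduces_priors():
    """With the likelihood off, the sampler's stationary law is the prior.

    A very small person count keeps the hierarchical prior Gibbs chain
    fast-mixing (the latents act as pseudo-data for the hyper layers).
    """
    data, _ = simulate_dataset(tiny_design(N=12, seed=3))
    cfg = McmcConfig(n_chains=2, n_iterations=6000, burn_in=500, thin=1, seed=4)
    res = fit(data, cfg, prior_only=True)

    mu = res.draws["mu_item"].reshape(-1, 3)
    assert mu[:, 0].mean() == pytest.approx(-2.197, abs=0.15)
    assert mu[:, 0].var() == pytest.approx(2.0, rel=0.25)
    assert (mu[:, 1] > 0).all()  # mu_delta truncation honoured
    assert mu[:, 1].mean() == pytest.approx(4.394, abs=0.2)  # truncation negligible
    assert mu[:, 2].mean() == pytest.approx(3.0, abs=0.15)

    phi = res.draws["phi"].ravel()
    assert phi.mean() == pytest.approx(0.0, abs=0.1)
    assert phi.var() == pytest.approx(1.0, rel=0.2)
    psi = res.draws["psi"].ravel()
    assert (psi > 0).all()
    assert psi.mean() == pytest.approx(1.0, abs=0.25)  # Gamma(1,1) mean

    nu = res.draws["nu"].reshape(-1, 2)
    assert (nu > 0).all()
    assert nu.mean() == pytest.approx(2 * np.sqrt(2 / np.pi), abs=0.3)  # half-normal, sd 2
    kappa = res.draws["kappa"].reshape(-1)
    assert kappa.mean() == pytest.approx(0.0, abs=0.3)
    assert kappa.var() == pytest.approx(4.0, rel=0.3)

    omega_prec = res.draws["omega"].reshape(-1) ** 2
    assert omega_prec.mean() == pytest.approx(1.0, abs=0.15)  # Gamma(1,1)


def test_summarize_layout(short_config, tiny_sim):
    data, _ = tiny_sim
    res = fit(data, short_config)
    table = summarize(res)
    assert "beta[0]" in table.index
    assert {"mean", "sd", "q2.5", "q97.5", "psrf"} <= set(table.columns)
    assert (table["q2.5"] <= table["mean"]).all()
    assert (table["mean"] <= table["q97.5"]).all()


def test_alpha_point_estimate_majority_rule():
    """Mastery frequency > 0.5 maps to 1; exact ties break toward 0."""
    from jtdina.mcmc import PosteriorResult

    draws = {"alpha": np.zeros((1, 10, 1, 2), dtype=np.int8)}
    draws["alpha"][0, :7, 0, 0] = 1   # frequency 0.7 -> 1
    draws["alpha"][0, :5, 0, 1] = 1   # frequency 0.5 -> 0 (tie)
    res = PosteriorResult(draws=draws, deviance=np.zeros((1, 10)),
                          config=McmcConfig(n_iterations=10, burn_in=0, thin=1),
                          priors=PriorSpec())
    est = res.point_estimates()["alpha"]
    assert est[0, 0] == 1
    assert est[0, 1] == 0


def test_constant_chain_point_estimate():
    from jtdina.mcmc import PosteriorResult

    draws = {"beta": np.full((2, 15, 3), 1.25)}
    res = PosteriorResult(draws=draws, deviance=np.zeros((2, 15)),
                          config=McmcConfig(n_iterations=15, burn_in=0, thin=1),
                          priors=PriorSpec())
    np.testing.assert_allclose(res.point_estimates()["beta"], 1.25)


def test_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(n_iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        McmcConfig(thin=0)
    with pytest.raises(ValueError):
        McmcConfig(model="bogus")
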