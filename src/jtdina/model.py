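"""Core model quantities for the joint testlet-DINA model.

The joint model couples two measurement models through layered covariance
structures:

* **Response accuracy (RA)** follows a testlet-DINA model: the log-odds of a
  correct response are ``beta_i + delta_i * eta_ni + sum_m u_im * gamma_nm``,
  where ``eta_ni`` is the conjunctive ("noisy-and") mastery indicator — person
  ``n`` must have mastered *every* attribute the Q-matrix requires for item
  ``i`` — and ``gamma_nm`` is a person-specific random testlet effect picking
  up local RA dependence among items sharing a stimulus.
* **Response times (RT)** follow a lognormal model: the natural log of the
  time spent on item ``i`` is normal with mean
  ``xi_i - tau_n - sum_m u_im * lambda_nm`` and standard deviation
  ``1/omega_i``; ``xi_i`` is the item's time intensity, ``tau_n`` the person's
  latent speed, ``lambda_nm`` the RT-side testlet effect and ``omega_i`` the
  time-kurtosis (precision-root) of the item.

Attribute mastery itself is governed by a higher-order logistic structure,
``logit P(alpha_nk = 1) = nu_k * theta_n - kappa_k``, with a general ability
``theta`` correlated with latent speed ``tau``.

Setting every testlet effect (or every testlet variance) to zero recovers the
joint responses-and-times DINA ("JRT-DINA") model, which serves throughout the
package as the baseline that ignores paired local item dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "QMatrix",
    "UMatrix",
    "ItemParameters",
    "PersonState",
    "TestletEffects",
    "StructuralParameters",
    "CovarianceLayers",
    "Dataset",
    "conjunctive_mastery",
    "mastery_matrix",
    "ra_success_probability",
    "rt_logdensity",
    "attribute_mastery_probability",
    "joint_loglikelihood",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _validate_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return a.astype(np.int8)


@dataclass(frozen=True)
class QMatrix:
    """Item-by-attribute design matrix: which skills each item requires.

    Every item must require at least one attribute, and every attribute must
    be required by at least one item (otherwise it is unidentifiable).
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        q = _validate_binary(self.entries, "Q-matrix")
        if q.ndim != 2:
            raise ValueError("Q-matrix must be 2-dimensional")
        if (q.sum(axis=1) < 1).any():
            raise ValueError("every Q-matrix item row needs >=1 attribute")
        if (q.sum(axis=0) < 1).any():
            raise ValueError("every Q-matrix attribute column needs >=1 item")
        object.__setattr__(self, "entries", q)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class UMatrix:
    """Item-by-testlet membership matrix.

    By default each item may belong to at most one testlet (single-source
    local dependence). Pass ``allow_multi_testlet=True`` to permit within-item
    multidimensional testlet structure, in which an item loads on several
    testlet effects simultaneously.
    """

    entries: np.ndarray
    allow_multi_testlet: bool = False

    def __post_init__(self) -> None:
        u = np.asarray(self.entries)
        if u.ndim != 2:
            raise ValueError("U-matrix must be 2-dimensional")
        u = _validate_binary(u, "U-matrix")
        if not self.allow_multi_testlet and (u.sum(axis=1) > 1).any():
            bad = int(np.where(u.sum(axis=1) > 1)[0][0])
            raise ValueError(
                f"U-matrix row {bad} belongs to multiple testlets; "
                "pass allow_multi_testlet=True for within-item "
                "multidimensional testlet structure"
            )
        object.__setattr__(self, "entries", u)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_testlets(self) -> int:
        return self.entries.shape[1]


@dataclass
class ItemParameters:
    """Per-item parameters of the two measurement models.

    ``beta`` (logit intercept) and ``delta`` (logit interaction) parameterise
    the RA model; the DINA guessing probability is ``expit(beta)`` and the
    slip probability ``1 - expit(beta + delta)``. ``xi`` is the RT
    time-intensity in log-seconds and ``omega`` the time-kurtosis; the
    residual SD of log time is ``1/omega``.
    """

    beta: np.ndarray
    delta: np.ndarray
    xi: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        self.xi = np.atleast_1d(np.asarray(self.xi, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if not (
            self.beta.shape == self.delta.shape == self.xi.shape == self.omega.shape
        ):
            raise ValueError("item parameter vectors must share a length")
        if (self.omega <= 0).any():
            raise ValueError("omega (time-kurtosis) must be strictly positive")

    @property
    def n_items(self) -> int:
        return self.beta.shape[0]

    @property
    def guess(self) -> np.ndarray:
        """Guessing probability per item, expit(beta)."""
        return expit(self.beta)

    @property
    def slip(self) -> np.ndarray:
        """Slip probability per item, 1 - expit(beta + delta)."""
        return 1.0 - expit(self.beta + self.delta)


@dataclass
class PersonState:
    """Per-person latents: general ability, latent speed, attribute pattern."""

    theta: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray  # (N, K) binary

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        self.alpha = _validate_binary(np.atleast_2d(self.alpha), "alpha")
        n = self.theta.shape[0]
        if self.tau.shape[0] != n or self.alpha.shape[0] != n:
            raise ValueError("theta, tau and alpha must agree on person count")

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.alpha.shape[1]


@dataclass
class TestletEffects:
    """Paired person-by-testlet random effects (gamma for RA, lam for RT)."""

    __test__ = False  # not a test case despite the name

    gamma: np.ndarray  # (N, M)
    lam: np.ndarray  # (N, M)

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.lam = np.atleast_2d(np.asarray(self.lam, dtype=float))
        if self.gamma.shape != self.lam.shape:
            raise ValueError("gamma and lambda must share shape (N, M)")

    @classmethod
    def zeros(cls, n_persons: int, n_testlets: int) -> "TestletEffects":
        shape = (n_persons, max(n_testlets, 0))
        return cls(np.zeros(shape), np.zeros(shape))

    @property
    def n_testlets(self) -> int:
        return self.gamma.shape[1]


@dataclass
class StructuralParameters:
    """Higher-order structure: slope nu_k > 0 and difficulty kappa_k per attribute."""

    nu: np.ndarray
    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        if self.nu.shape != self.kappa.shape:
            raise ValueError("nu and kappa must share length K")
        if (self.nu <= 0).any():
            raise ValueError("nu must be strictly positive (sign identification)")


def person_covariance(phi: float, psi: float) -> np.ndarray:
    """Reconstruct the 2x2 person covariance from its Cholesky-style factors.

    ``Sigma_person = Delta @ Delta.T`` with ``Delta = [[1, 0], [phi, psi]]``,
    so the ability variance is pinned to exactly 1 for identification and the
    speed variance is ``phi**2 + psi**2``.
    """
    if psi <= 0:
        raise ValueError("psi must be positive")
    delta = np.array([[1.0, 0.0], [phi, psi]])
    return delta @ delta.T


@dataclass
class CovarianceLayers:
    """Hyper-level covariance structure of the joint model.

    ``mu_item``/``Sigma_item`` govern the trivariate normal of (beta, delta,
    xi); the person layer is parameterised by the lower-triangular factors
    ``phi`` (free) and ``psi`` (positive) so that the reconstructed
    Sigma_person always has unit ability variance; ``Sigma_testlet`` stacks
    one 2x2 covariance per testlet for the paired effects (gamma, lambda).
    The means of theta and tau are fixed at zero.
    """

    mu_item: np.ndarray
    Sigma_item: np.ndarray
    phi: float
    psi: float
    Sigma_testlet: np.ndarray = field(default_factory=lambda: np.zeros((0, 2, 2)))

    def __post_init__(self) -> None:
        self.mu_item = np.asarray(self.mu_item, dtype=float).reshape(3)
        self.Sigma_item = np.asarray(self.Sigma_item, dtype=float).reshape(3, 3)
        self.Sigma_testlet = np.asarray(self.Sigma_testlet, dtype=float).reshape(-1, 2, 2)
        _check_spd(self.Sigma_item, "Sigma_item")
        for m in range(self.Sigma_testlet.shape[0]):
            _check_spd(self.Sigma_testlet[m], f"Sigma_testlet[{m}]")
        if self.psi <= 0:
            raise ValueError("psi must be positive")

    @property
    def Sigma_person(self) -> np.ndarray:
        return person_covariance(self.phi, self.psi)


def _check_spd(a: np.ndarray, name: str) -> None:
    if not np.allclose(a, a.T):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc


@dataclass
class Dataset:
    """Paired observed matrices plus the Q/U design.

    ``Y`` is the N-by-I binary accuracy matrix, ``logT`` the matching matrix
    of natural-log response times (seconds logged on ingest). No missing
    cells are allowed: rows with missing entries must be dropped before
    construction (complete-case contract).
    """

    Y: np.ndarray
    logT: np.ndarray
    Q: QMatrix
    U: UMatrix

    def __post_init__(self) -> None:
        self.Y = _validate_binary(np.atleast_2d(self.Y), "Y")
        self.logT = np.atleast_2d(np.asarray(self.logT, dtype=float))
        if self.Y.shape != self.logT.shape:
            raise ValueError("Y and logT must share shape (N, I)")
        if not np.isfinite(self.logT).all():
            raise ValueError("logT must be finite (no missing cells)")
        if self.Q.n_items != self.Y.shape[1]:
            raise ValueError("Q-matrix item count must match Y columns")
        if self.U.n_items != self.Y.shape[1]:
            raise ValueError("U-matrix item count must match Y columns")

    @property
    def n_persons(self) -> int:
        return self.Y.shape[0]

    @property
    def n_items(self) -> int:
        return self.Y.shape[1]


# ---------------------------------------------------------------------------
# model quantities
# ---------------------------------------------------------------------------


def conjunctive_mastery(alpha, q) -> int:
    """DINA mastery indicator ``prod_k alpha_k ** q_k`` for one person/item.

    Returns 1 iff every attribute required by ``q`` is mastered in ``alpha``.
    An item requiring no attributes yields 1 (empty product).
    """
    alpha = np.asarray(alpha)
    q = np.asarray(q)
    if alpha.shape != q.shape:
        raise ValueError("alpha and q must share length K")
    return int(np.all(alpha[q == 1] == 1))


def mastery_matrix(alpha: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Vectorised conjunctive mastery: (N, K) x (I, K) -> (N, I) in {0,1}."""
    alpha = np.asarray(alpha, dtype=np.int64)
    Q = np.asarray(Q, dtype=np.int64)
    need = Q.sum(axis=1)
    return (alpha @ Q.T == need[None, :]).astype(np.int8)


def ra_success_probability(beta, delta, eta, testlet_contrib=0.0) -> np.ndarray:
    """Success probability of the testlet-DINA RA model.

    ``expit(beta + delta * eta + testlet_contrib)``, where ``testlet_contrib``
    is the summed testlet effect ``sum_m u_im * gamma_nm``. Strictly inside
    (0, 1) for finite inputs.
    """
    return expit(
        np.asarray(beta, dtype=float)
        + np.asarray(delta, dtype=float) * np.asarray(eta, dtype=float)
        + np.asarray(testlet_contrib, dtype=float)
    )


def rt_logdensity(logt, xi, tau, lambda_contrib, omega) -> np.ndarray:
    """Log density of log response time under the lognormal RT testlet model.

    Normal in ``logt`` with mean ``xi - tau - lambda_contrib`` and variance
    ``omega**-2``; the equivalent density of the raw time t carries an extra
    Jacobian factor 1/t.
    """
    omega = np.asarray(omega, dtype=float)
    if (omega <= 0).any():
        raise ValueError("omega must be strictly positive")
    mean = (
        np.asarray(xi, dtype=float)
        - np.asarray(tau, dtype=float)
        - np.asarray(lambda_contrib, dtype=float)
    )
    z = omega * (np.asarray(logt, dtype=float) - mean)
    return np.log(omega) - 0.5 * _LOG_2PI - 0.5 * z * z


def attribute_mastery_probability(theta, nu, kappa) -> np.ndarray:
    """Higher-order mastery probability ``expit(nu * theta - kappa)``."""
    return expit(np.asarray(nu, dtype=float) * np.asarray(theta, dtype=float)
                 - np.asarray(kappa, dtype=float))


def _bernoulli_loglik(y: np.ndarray, logit_p: np.ndarray) -> np.ndarray:
    # y*x - log(1 + e^x), stable for large |x|
    return y * logit_p - np.logaddexp(0.0, logit_p)


def joint_loglikelihood(
    data: Dataset,
    items: ItemParameters,
    persons: PersonState,
    testlets: TestletEffects | None = None,
    model: str = "joint_testlet",
) -> float:
    """Conditional log likelihood of (Y, logT) given every latent quantity.

    Sums Bernoulli log mass of each response (via the testlet-DINA success
    probability) and the normal log density of each log time. Under
    ``model="jrt"`` all testlet effects are forced to zero, giving the
    JRT-DINA baseline likelihood.
    """
    if model not in ("joint_testlet", "jrt"):
        raise ValueError(f"unknown model flag {model!r}")
    N, I = data.Y.shape
    if items.n_items != I:
        raise ValueError("item parameter count must match data")
    if persons.n_persons != N:
        raise ValueError("person count must match data")
    U = data.U.entries.astype(float)
    if model == "jrt" or testlets is None or testlets.n_testlets == 0:
        tc = np.zeros((N, I))
        lc = np.zeros((N, I))
    else:
        if testlets.gamma.shape != (N, data.U.n_testlets):
            raise ValueError("testlet effects must be (N, M)")
        tc = testlets.gamma @ U.T
        lc = testlets.lam @ U.T
    eta = mastery_matrix(persons.alpha, data.Q.entries)
    logit_p = items.beta[None, :] + items.delta[None, :] * eta + tc
    ll_ra = _bernoulli_loglik(data.Y.astype(float), logit_p).sum()
    ll_rt = rt_logdensity(
        data.logT, items.xi[None, :], persons.tau[:, None], lc, items.omega[None, :]
    ).sum()
    return float(ll_ra + ll_rt)
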