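"""Synthetic paired RA+RT data with known generating truth.

The default design mirrors the recovery-study conditions the package is
benchmarked under: 1,000 respondents, 30 items measuring 5 attributes, the
last 20 items evenly split into 4 testlets (items 11-15, 16-20, 21-25,
26-30), moderate paired testlet effects with variance 0.5 and cross
correlation -0.5, item parameters drawn from a trivariate normal centred at
(-2.197, 4.394, 4.000), time-kurtosis omega ~ N(2, 0.25) truncated positive,
person (theta, tau) bivariate normal with unit ability variance, speed
variance 0.25 and correlation -0.5, higher-order slopes nu_k = 1.5 and
difficulties kappa = (-1, -0.5, 0, 0.5, 1).

All ``N(a, b)`` second arguments are read as variances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    CovarianceLayers,
    Dataset,
    ItemParameters,
    PersonState,
    QMatrix,
    StructuralParameters,
    TestletEffects,
    UMatrix,
    attribute_mastery_probability,
    mastery_matrix,
    ra_success_probability,
)

__all__ = [
    "SimulationDesign",
    "TruthRecord",
    "default_design",
    "default_q_matrix",
    "default_u_matrix",
    "simulate_persons",
    "simulate_items",
    "simulate_testlet_effects",
    "simulate_dataset",
]


def _spd(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc
    return a


@dataclass
class SimulationDesign:
    """Full generating specification for one synthetic dataset."""

    N: int
    I: int
    K: int
    M: int
    Q: QMatrix
    U: UMatrix
    mu_item: np.ndarray
    Sigma_item: np.ndarray
    omega_mean: float
    omega_var: float
    Sigma_person: np.ndarray
    Sigma_testlet: np.ndarray  # (M, 2, 2)
    nu: np.ndarray
    kappa: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_item = np.asarray(self.mu_item, dtype=float).reshape(3)
        self.Sigma_item = _spd(self.Sigma_item, "Sigma_item")
        self.Sigma_person = _spd(self.Sigma_person, "Sigma_person")
        if not np.isclose(self.Sigma_person[0, 0], 1.0):
            raise ValueError("Sigma_person must have unit ability variance")
        self.Sigma_testlet = np.asarray(self.Sigma_testlet, dtype=float).reshape(-1, 2, 2)
        for m in range(self.Sigma_testlet.shape[0]):
            _spd(self.Sigma_testlet[m], f"Sigma_testlet[{m}]")
        self.nu = np.asarray(self.nu, dtype=float).reshape(self.K)
        self.kappa = np.asarray(self.kappa, dtype=float).reshape(self.K)
        if (self.nu <= 0).any():
            raise ValueError("nu must be positive")
        if self.Q.n_items != self.I or self.Q.n_attributes != self.K:
            raise ValueError("Q shape must be (I, K)")
        if self.U.n_items != self.I or self.U.n_testlets != self.M:
            raise ValueError("U shape must be (I, M)")
        if self.Sigma_testlet.shape[0] != self.M:
            raise ValueError("one 2x2 testlet covariance per testlet required")


@dataclass
class TruthRecord:
    """Every generating latent and parameter, kept for recovery scoring."""

    items: ItemParameters
    persons: PersonState
    testlets: TestletEffects
    structural: StructuralParameters
    covariances: CovarianceLayers
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "beta": self.items.beta.tolist(),
            "delta": self.items.delta.tolist(),
            "xi": self.items.xi.tolist(),
            "omega": self.items.omega.tolist(),
            "theta": self.persons.theta.tolist(),
            "tau": self.persons.tau.tolist(),
            "alpha": self.persons.alpha.tolist(),
            "gamma": self.testlets.gamma.tolist(),
            "lam": self.testlets.lam.tolist(),
            "nu": self.structural.nu.tolist(),
            "kappa": self.structural.kappa.tolist(),
            "mu_item": self.covariances.mu_item.tolist(),
            "Sigma_item": self.covariances.Sigma_item.tolist(),
            "phi": self.covariances.phi,
            "psi": self.covariances.psi,
            "Sigma_testlet": self.covariances.Sigma_testlet.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            items=ItemParameters(
                np.array(d["beta"]), np.array(d["delta"]),
                np.array(d["xi"]), np.array(d["omega"]),
            ),
            persons=PersonState(
                np.array(d["theta"]), np.array(d["tau"]),
                np.array(d["alpha"], dtype=np.int8),
            ),
            testlets=TestletEffects(np.array(d["gamma"]), np.array(d["lam"])),
            structural=StructuralParameters(np.array(d["nu"]), np.array(d["kappa"])),
            covariances=CovarianceLayers(
                np.array(d["mu_item"]), np.array(d["Sigma_item"]),
                d["phi"], d["psi"], np.array(d["Sigma_testlet"]),
            ),
            seed=d["seed"],
        )


def default_q_matrix() -> QMatrix:
    """Default 30x5 Q-matrix.

    Items 1-10 each measure a single attribute, cycling 1..5 twice; items
    11-20 measure attribute pairs and items 21-30 attribute triples in a
    balanced cycle, so each attribute loads on 12 items and every column is
    anchored by single-attribute items.
    """
    K = 5
    rows = []
    for i in range(10):
        r = np.zeros(K, dtype=np.int8)
        r[i % K] = 1
        rows.append(r)
    pairs = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0),
             (0, 2), (1, 3), (2, 4), (3, 0), (4, 1)]
    for a, b in pairs:
        r = np.zeros(K, dtype=np.int8)
        r[[a, b]] = 1
        rows.append(r)
    triples = [(0, 1, 2), (1, 2, 3), (2, 3, 4), (3, 4, 0), (4, 0, 1),
               (0, 1, 3), (1, 2, 4), (2, 3, 0), (3, 4, 1), (4, 0, 2)]
    for t in triples:
        r = np.zeros(K, dtype=np.int8)
        r[list(t)] = 1
        rows.append(r)
    return QMatrix(np.vstack(rows))


def default_u_matrix() -> UMatrix:
    """Default 30x4 U-matrix: items 11-15, 16-20, 21-25, 26-30 form testlets."""
    u = np.zeros((30, 4), dtype=np.int8)
    for m in range(4):
        u[10 + 5 * m: 15 + 5 * m, m] = 1
    return UMatrix(u)


def default_design(seed: int = 0) -> SimulationDesign:
    """The benchmark generating design (see module docstring)."""
    sd_item = np.array([1.0, 1.0, 0.5])
    corr_item = np.array([
        [1.0, -0.8, -0.5],
        [-0.8, 1.0, 0.3],
        [-0.5, 0.3, 1.0],
    ])
    Sigma_item = corr_item * np.outer(sd_item, sd_item)
    Sigma_person = np.array([[1.0, -0.25], [-0.25, 0.25]])  # rho_theta_tau = -0.5
    Sigma_testlet = np.broadcast_to(
        np.array([[0.50, -0.25], [-0.25, 0.50]]), (4, 2, 2)
    ).copy()
    return SimulationDesign(
        N=1000, I=30, K=5, M=4,
        Q=default_q_matrix(), U=default_u_matrix(),
        mu_item=np.array([-2.197, 4.394, 4.000]),
        Sigma_item=Sigma_item,
        omega_mean=2.0, omega_var=0.25,
        Sigma_person=Sigma_person,
        Sigma_testlet=Sigma_testlet,
        nu=np.full(5, 1.5),
        kappa=np.array([-1.0, -0.5, 0.0, 0.5, 1.0]),
        seed=seed,
    )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Hierarchical RNG split: stable sub-streams per simulation stage."""
    root = np.random.SeedSequence(seed)
    names = ("persons", "items", "testlets", "observations")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def simulate_persons(design: SimulationDesign, rng: np.random.Generator) -> PersonState:
    """Draw (theta, tau) bivariate normal, then alpha | theta Bernoulli."""
    mean = np.zeros(2)
    draws = rng.multivariate_normal(mean, design.Sigma_person, size=design.N,
                                    method="cholesky")
    theta, tau = draws[:, 0], draws[:, 1]
    p = attribute_mastery_probability(theta[:, None], design.nu[None, :],
                                      design.kappa[None, :])
    alpha = (rng.random((design.N, design.K)) < p).astype(np.int8)
    return PersonState(theta, tau, alpha)


def simulate_items(design: SimulationDesign, rng: np.random.Generator) -> ItemParameters:
    """Draw (beta, delta, xi) trivariate normal and omega truncated normal."""
    psi = rng.multivariate_normal(design.mu_item, design.Sigma_item, size=design.I,
                                  method="cholesky")
    omega = rng.normal(design.omega_mean, np.sqrt(design.omega_var), size=design.I)
    # omega is a precision root; resample the (astronomically rare) negatives
    while (omega <= 0).any():
        bad = omega <= 0
        omega[bad] = rng.normal(design.omega_mean, np.sqrt(design.omega_var),
                                size=int(bad.sum()))
    return ItemParameters(psi[:, 0], psi[:, 1], psi[:, 2], omega)


def simulate_testlet_effects(
    design: SimulationDesign, N: int, rng: np.random.Generator
) -> TestletEffects:
    """Draw paired (gamma, lambda) per person/testlet, independent across both."""
    gamma = np.zeros((N, design.M))
    lam = np.zeros((N, design.M))
    for m in range(design.M):
        g = rng.multivariate_normal(np.zeros(2), design.Sigma_testlet[m], size=N,
                                    method="cholesky")
        gamma[:, m], lam[:, m] = g[:, 0], g[:, 1]
    return TestletEffects(gamma, lam)


def simulate_dataset(design: SimulationDesign) -> tuple[Dataset, TruthRecord]:
    """Generate one full dataset plus its generating truth; seed-reproducible."""
    streams = _streams(design.seed)
    persons = simulate_persons(design, streams["persons"])
    items = simulate_items(design, streams["items"])
    testlets = simulate_testlet_effects(design, design.N, streams["testlets"])
    obs_rng = streams["observations"]

    U = design.U.entries.astype(float)
    eta = mastery_matrix(persons.alpha, design.Q.entries)
    tc = testlets.gamma @ U.T
    lc = testlets.lam @ U.T
    p = ra_success_probability(items.beta[None, :], items.delta[None, :], eta, tc)
    Y = (obs_rng.random((design.N, design.I)) < p).astype(np.int8)
    mean = items.xi[None, :] - persons.tau[:, None] - lc
    logT = obs_rng.normal(mean, 1.0 / items.omega[None, :])

    phi = design.Sigma_person[0, 1]
    psi = float(np.sqrt(design.Sigma_person[1, 1] - phi ** 2))
    truth = TruthRecord(
        items=items,
        persons=persons,
        testlets=testlets,
        structural=StructuralParameters(design.nu, design.kappa),
        covariances=CovarianceLayers(
            design.mu_item, design.Sigma_item, float(phi), psi, design.Sigma_testlet
        ),
        seed=design.seed,
    )
    data = Dataset(Y, logT, design.Q, design.U)
    return data, truth


def with_testlet_variance(design: SimulationDesign, variance: float,
                          covariance: float | None = None) -> SimulationDesign:
    """Convenience: same design with every testlet covariance replaced."""
    if covariance is None:
        covariance = 0.0 if variance == 0 else -0.5 * variance
    sigma = np.broadcast_to(
        np.array([[variance, covariance], [covariance, variance]]),
        (design.M, 2, 2),
    ).copy()
    if variance == 0:
        sigma = np.zeros((design.M, 2, 2))
    return replace(design, Sigma_testlet=sigma) if variance > 0 else _zero_testlets(design)


def _zero_testlets(design: SimulationDesign) -> SimulationDesign:
    # A zero matrix is not SPD; represent "no testlet effect" with M=0 design
    u = UMatrix(np.zeros((design.I, 0), dtype=np.int8))
    return replace(design, M=0, U=u, Sigma_testlet=np.zeros((0, 2, 2)))
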