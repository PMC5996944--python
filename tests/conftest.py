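import numpy as np
import pytest

from jtdina.model import Dataset, QMatrix, UMatrix
from jtdina.mcmc import McmcConfig
from jtdina.simulate import SimulationDesign, simulate_dataset


def tiny_design(N=60, seed=0, M=1):
    """Small 6-item, 2-attribute design with one testlet (items 4-6)."""
    Q = QMatrix(np.array([
        [1, 0], [0, 1], [1, 1],
        [1, 0], [0, 1], [1, 1],
    ]))
    u = np.zeros((6, M), dtype=np.int8)
    if M:
        u[3:, 0] = 1
    U = UMatrix(u)
    return SimulationDesign(
        N=N, I=6, K=2, M=M, Q=Q, U=U,
        mu_item=np.array([-2.197, 4.394, 4.0]),
        Sigma_item=np.diag([0.25, 0.25, 0.25]),
        omega_mean=2.0, omega_var=0.25,
        Sigma_person=np.array([[1.0, -0.25], [-0.25, 0.25]]),
        Sigma_testlet=np.broadcast_to(
            np.array([[0.5, -0.25], [-0.25, 0.5]]), (M, 2, 2)).copy(),
        nu=np.array([1.5, 1.5]),
        kappa=np.array([-0.5, 0.5]),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate_dataset(tiny_design(seed=11))


@pytest.fixture(scope="session")
def short_config():
    return McmcConfig(n_chains=2, n_iterations=900, burn_in=400, thin=5, seed=5)


@pytest.fixture(scope="session")
def recovery_study():
    """Shared scaled recovery study (R=5, both models) at the benchmark design.

    Expensive; computed once per session and reused by every recovery-level
    check.
    """
    from jtdina.recovery import run_recovery_study, scaled_config

    report, fits, data = run_recovery_study(
        R=5, config=scaled_config(), base_seed=1, keep_first_fit=True
    )
    return report, fits, data
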