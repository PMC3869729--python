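import numpy as np
import pytest

from trajmode import (
    ModeSchedule,
    ModelLabel,
    PolynomialPotential,
    SimConfig,
    simulate,
)
from trajmode.bench import simulate_ensemble


@pytest.fixture(scope="session")
def free_traj_500():
    """One noiseless 500-frame free Brownian trajectory at D = 0.1, dt = 50 ms."""
    cfg = SimConfig(D=0.1, dt=0.05, n_frames=500, sigma=0.0, seed=101)
    return simulate(cfg, ModeSchedule.free(500))


@pytest.fixture(scope="session")
def spring_traj_long():
    """Long spring-confined trajectory (k = 1 kBT/um^2) for parameter recovery."""
    pot = PolynomialPotential.spring(1.0)
    cfg = SimConfig(D=0.1, dt=0.05, n_frames=2000, sigma=0.0, seed=202)
    return simulate(cfg, ModeSchedule.confined(2000, pot))


@pytest.fixture(scope="session")
def spring_pool():
    """Pooled stationary spring ensemble (k = 1 kBT/um^2): 12 x 5000 frames."""
    pot = PolynomialPotential.spring(1.0)
    out = []
    for i in range(12):
        cfg = SimConfig(D=0.1, dt=0.05, n_frames=5000, sigma=0.0, seed=300 + i)
        out.append(simulate(cfg, ModeSchedule.confined(5000, pot)))
    return out


@pytest.fixture(scope="session")
def mixed_trajs():
    """A few trajectories of each true mode at the default study conditions."""
    trajs = []
    for truth, seed in [
        (ModelLabel.FREE, 410),
        (ModelLabel.SPRING2, 420),
        (ModelLabel.QUARTIC4, 430),
    ]:
        trajs.extend(simulate_ensemble(truth, count=3, n_frames=300, seed=seed))
    return trajs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
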