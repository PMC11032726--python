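import numpy as np
import pytest

from trajkit import SimulationSpec, Trajectory, simulate


@pytest.fixture
def line_1d():
    """Unit-step straight line in 1-D, N=20, dt=1."""
    t = np.arange(20.0)
    return Trajectory(times=t, positions=t.copy(), id="line")


@pytest.fixture
def l_path():
    """The 2-D L-shaped path (0,0) -> (1,0) -> (1,1)."""
    return Trajectory(
        times=[0.0, 1.0, 2.0], positions=[[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]
    )


@pytest.fixture
def brownian_2d():
    """A 2-D Brownian trajectory, D=1, dt=1, N=10^4, fixed seed."""
    return simulate(SimulationSpec(mode="normal", n_points=10_000, dim=2, seed=42))


def random_walk(seed: int, n: int = 100, dim: int = 2, dt: float = 1.0) -> Trajectory:
    """Deterministic Gaussian random walk helper for property tests."""
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n - 1, dim))
    pos = np.vstack([np.zeros(dim), np.cumsum(steps, axis=0)])
    return Trajectory(times=dt * np.arange(n), positions=pos)
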