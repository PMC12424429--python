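import math

import numpy as np
import pytest

from smtrap.trajio import DEFAULT_DT, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def brownian_track(
    n: int,
    d: float,
    rng: np.random.Generator,
    sigma_nm: float = 0.0,
    dt: float = DEFAULT_DT,
    tid: str = "t0",
    cell: str = "c0",
) -> Trajectory:
    """Free 2-D Brownian trajectory with optional localization noise."""
    steps = rng.normal(0.0, math.sqrt(2.0 * d * dt), size=(n - 1, 2))
    xy = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    xy = xy + rng.normal(0.0, sigma_nm / 1000.0, size=(n, 2))
    return Trajectory(cell, "green", tid, np.arange(n), xy, dt)


def stationary_track(
    n: int,
    rng: np.random.Generator,
    sigma_nm: float = 14.0,
    dt: float = DEFAULT_DT,
    tid: str = "t0",
    cell: str = "c0",
) -> Trajectory:
    """Stationary emitter observed with localization noise only."""
    xy = rng.normal(0.0, sigma_nm / 1000.0, size=(n, 2))
    return Trajectory(cell, "green", tid, np.arange(n), xy, dt)
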