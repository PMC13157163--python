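import numpy as np
import pytest

from fishnav.arena import ArenaConfig, Environment, generate_environment


@pytest.fixture
def empty_env():
    """4x4 arena with no corals, start/target 1 m apart on the x axis."""
    cfg = ArenaConfig(n_corals=0)
    return Environment(
        config=cfg,
        coral_centers=np.empty((0, 2)),
        start=np.array([-0.5, 0.0]),
        target=np.array([0.5, 0.0]),
    )


@pytest.fixture
def single_coral_env():
    """One coral 1 m ahead of the origin on the +x axis."""
    cfg = ArenaConfig(n_corals=1)
    return Environment(
        config=cfg,
        coral_centers=np.array([[1.0, 0.0]]),
        start=np.array([0.0, 0.0]),
        target=np.array([1.8, 0.0]),
    )


@pytest.fixture
def default_env():
    return generate_environment(ArenaConfig(n_corals=25), seed=0)
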