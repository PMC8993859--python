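import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mobinfo import SyntheticConfig, Trajectory, generate_population


def make_traj(locations, timestamps=None, user="u", **kw):
    if timestamps is None:
        timestamps = np.arange(len(list(locations)), dtype=float)
    return Trajectory(user, locations, timestamps, **kw)


@pytest.fixture
def traj_factory():
    return make_traj


@pytest.fixture(scope="session")
def small_population():
    """A small planted population shared by network / pipeline tests."""
    cfg = SyntheticConfig(
        n_egos=3,
        n_social_per_ego=10,
        n_coloc_per_ego=10,
        n_background=5,
        n_events=250,
        seed=42,
    )
    return cfg, *generate_population(cfg)
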