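import numpy as np
import pytest

from sptstates import synthetic_data as sd
from sptstates import tracking_io as tio
from sptstates.state_hmm import StateModel


@pytest.fixture(scope="session")
def interphase_model():
    return sd.interphase_h1_model()


@pytest.fixture(scope="session")
def metaphase_model():
    return sd.metaphase_h1_model()


@pytest.fixture(scope="session")
def single_state_tracks():
    """Pure Brownian tracks, D = 0.114 um^2/s, no localization noise."""
    model = StateModel(D=[0.114], transmat=[[1.0]], frame_interval=0.05)
    spec = sd.SimulationSpec(
        model=model, n_tracks=2500, mean_track_length=42.0, loc_sd=0.0, seed=101
    )
    return sd.simulate_tracks(spec)


@pytest.fixture(scope="session")
def interphase_tracks(interphase_model):
    """~4e4 ground-truth-labelled steps from the three-state model."""
    spec = sd.SimulationSpec(
        model=interphase_model,
        n_tracks=2000,
        mean_track_length=21.0,
        loc_sd=0.0,
        seed=11,
    )
    return sd.simulate_tracks(spec)


@pytest.fixture
def tiny_tracks():
    """Three hand-built tracks of lengths 3, 5, 8."""
    import pandas as pd

    rows = []
    for tid, n in [(0, 3), (1, 5), (2, 8)]:
        for f in range(n):
            rows.append({"track": tid, "frame": f, "x": 0.1 * f + tid, "y": 0.05 * f})
    return tio.TrajectorySet(pd.DataFrame(rows), frame_interval=0.05)


def rng(seed=0):
    return np.random.default_rng(seed)
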