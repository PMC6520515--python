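import numpy as np
import pandas as pd
import pytest

from whiskmap import BehaviorPolicy, SimConfig, generate_session
from whiskmap.simulate import noiseless


@pytest.fixture(scope="session")
def short_config() -> SimConfig:
    """Trial layout sized down for test speed: 800 ms trials, pole at 300 ms."""
    return SimConfig(n_trials=100, trial_duration=800, pole_onset=300)


@pytest.fixture(scope="session")
def noiseless_session(short_config):
    cfg = noiseless(short_config)
    return generate_session(cfg, BehaviorPolicy(), np.random.default_rng(42),
                            session_id="nless")


@pytest.fixture(scope="session")
def noisy_session(short_config):
    return generate_session(short_config, BehaviorPolicy(),
                            np.random.default_rng(43), session_id="noisy")


def frame_df(angle=None, kappa=None, dist=None, quality=None, n=None):
    """Hand-build a frame table; unspecified columns get benign defaults."""
    for arr in (angle, kappa, dist, quality):
        if arr is not None:
            n = len(arr)
            break
    assert n is not None
    return pd.DataFrame({
        "session_id": "s",
        "trial_idx": 0,
        "t_ms": np.arange(n),
        "angle_deg": angle if angle is not None else np.zeros(n),
        "kappa_per_mm": kappa if kappa is not None else np.zeros(n),
        "pole_dist": dist if dist is not None else np.full(n, 3.0),
        "quality": quality if quality is not None else ["ok"] * n,
    })
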