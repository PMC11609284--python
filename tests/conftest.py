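import numpy as np
import pandas as pd
import pytest

from cardiostop.config import SessionConfig
from cardiostop.montage import load_montage, subset_montage
from cardiostop.simulate import simulate_session
from cardiostop.stats import build_adjacency

# Central-channel subset used for fast multi-subject experiments; covers
# every ROI except the outer P2 electrodes.
CH24 = [
    "AFz", "F3", "F1", "Fz", "F2", "F4", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C3", "C1", "Cz", "C2", "C4", "CP3", "CP1", "CPz", "CP2", "CP4", "P1", "Pz", "P2",
]


def mini_config(**overrides) -> SessionConfig:
    """Two-block (systole, diastole) scaled-down session at 250 Hz."""
    kw = dict(
        n_blocks=2,
        trials_per_block=36,
        go_per_block=18,
        stop_per_block=18,
        fs=250.0,
        channels=list(CH24),
        counterbalance_index=0,
    )
    kw.update(overrides)
    return SessionConfig(**kw)


@pytest.fixture(scope="session")
def montage64() -> pd.DataFrame:
    return load_montage()


@pytest.fixture(scope="session")
def montage24(montage64) -> pd.DataFrame:
    return subset_montage(montage64, CH24)


@pytest.fixture(scope="session")
def adjacency24(montage24):
    return build_adjacency(montage24, threshold_cm=5.0)


@pytest.fixture(scope="session")
def clean_mini_session():
    """Noise-free scaled-down session with EEG: every injected component
    is exactly recoverable."""
    cfg = mini_config(
        trials_per_block=12, go_per_block=6, stop_per_block=6,
        noise_sd_uv=0.0, ecg_noise_sd_uv=0.0, trigger_jitter_sd_ms=0.0,
    )
    return simulate_session(cfg, seed=101)


@pytest.fixture(scope="session")
def noisy_mini_session():
    return simulate_session(mini_config(trials_per_block=18, go_per_block=9,
                                        stop_per_block=9), seed=202)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
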