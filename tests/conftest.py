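import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ctfeeg import SimConfig, make_montage, simulate_epochs
from ctfeeg.epochs import EpochedData


@pytest.fixture(scope="session")
def exp2_montage():
    return make_montage("exp2_27")


@pytest.fixture(scope="session")
def exp1_montage():
    return make_montage("exp1_23")


@pytest.fixture(scope="session")
def small_sim(exp2_montage):
    """A reduced 8-position dataset with ground truth (shared, read-only)."""
    cfg = SimConfig(n_trials_per_position=40, epoch_window=(-100.0, 400.0),
                    seed=11)
    epochs, truth = simulate_epochs(cfg, exp2_montage)
    return cfg, epochs, truth


@pytest.fixture(scope="session")
def noisefree_sim(exp2_montage):
    cfg = SimConfig(n_trials_per_position=10, epoch_window=(-100.0, 400.0),
                    noise_sd=0.0, seed=5)
    epochs, truth = simulate_epochs(cfg, exp2_montage)
    return cfg, epochs, truth


def toy_epochs(data, sfreq=250.0, labels=None, electrodes=None, t0_index=None):
    """Small hand-built EpochedData for arithmetic fixtures."""
    data = np.asarray(data, dtype=float)
    n, m, t = data.shape
    if t0_index is None:
        t0_index = t // 2
    times = (np.arange(t) - t0_index) / sfreq * 1000.0
    return EpochedData(
        data=data,
        times=times,
        sfreq=sfreq,
        labels=np.ones(n, dtype=int) if labels is None else labels,
        electrodes=[f"E{i + 1}" for i in range(m)]
        if electrodes is None else electrodes,
        meta=pd.DataFrame({"trial": np.arange(n)}),
    )
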