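import numpy as np
import pandas as pd
import pytest

from speechosc import EpochedEEG, SimulationSpec, make_synthetic_montage


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def montage16():
    return make_synthetic_montage(16)


@pytest.fixture()
def small_epochs(montage16):
    """Three clean 7-s epochs of a 10 Hz sinusoid at 500 Hz, tmin -3.5 s."""
    rate = 500.0
    t = np.arange(int(7 * rate)) / rate
    sig = np.sin(2 * np.pi * 10 * t)
    data = np.tile(sig, (3, 16, 1))
    trials = pd.DataFrame(
        {"onset_ms": [0.0] * 3, "duration_ms": [2000.0] * 3, "condition": ["speech"] * 3}
    )
    return EpochedEEG(
        data=data,
        rate=rate,
        ch_names=list(montage16),
        montage=montage16,
        trials=trials,
        tmin_ms=-3500.0,
    )


@pytest.fixture()
def tracking_spec():
    """Noiseless theta-band embedding with a single in-band modulation peak."""
    return SimulationSpec(
        n_trials=10,
        trial_ms=3000.0,
        n_channels=4,
        seed=2,
        snr=1e6,
        embed_lag_ms=100.0,
        envelope_peaks=(1.2,),
        embed_channels=("E1",),
        pac=(),
    )
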