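import numpy as np
import pytest

import pocketgait as pg


@pytest.fixture
def config():
    return pg.PipelineConfig()


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free identity-orientation 45-s trial with ground truth."""
    cfg = pg.SimulationConfig(seed=11)
    return pg.simulate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """Randomly oriented trial with 15%-of-signal-SD accelerometer noise."""
    _, truth0 = pg.simulate_trial(pg.SimulationConfig(seed=11))
    noise = 0.15 * float(np.std(truth0.az_earth))
    cfg = pg.SimulationConfig(accel_noise_sd=noise, gyro_noise_sd=0.01,
                              orientation="random", seed=11)
    return pg.simulate_trial(cfg)


def recording_frame(n=4500, fs=100.0, seed=0):
    """Minimal valid recording as a pandas DataFrame (for I/O tests)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    df = pd.DataFrame({"t": t})
    for col in ("ax", "ay", "az", "gx", "gy", "gz"):
        df[col] = rng.normal(size=n)
    quat = rng.normal(size=(n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    for i, col in enumerate(("qw", "qx", "qy", "qz")):
        df[col] = quat[:, i]
    return df
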