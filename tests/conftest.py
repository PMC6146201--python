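import numpy as np
import pytest

from n170trial import EpochSet, SimulationConfig, make_session
from n170trial.preprocess import run_preprocessing


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=0)


@pytest.fixture(scope="session")
def session_epochs(default_config) -> EpochSet:
    """One subject's raw synthetic session (default design: 480 trials)."""
    return make_session(default_config, 0)


@pytest.fixture(scope="session")
def clean_epochs(session_epochs) -> EpochSet:
    """The same session after default preprocessing."""
    epochs, _ = run_preprocessing(session_epochs)
    return epochs


@pytest.fixture()
def toy_epochs() -> EpochSet:
    """Tiny deterministic epoch set: 4 trials x 2 channels x 10 samples at
    250 Hz starting at -20 ms."""
    times = -20.0 + 4.0 * np.arange(10)
    data = np.zeros((4, 2, 10))
    data[0] += 5.0                       # constant trace
    data[1, 0] = np.arange(10)           # ramp on channel A
    data[2, 1, 3] = 150.0                # artifact spike
    data[3, 0] = -1.0
    return EpochSet(
        data=data,
        labels=np.array(["positive", "negative", "positive", "negative"],
                        dtype=object),
        channels=["A", "B"],
        times=times,
        sampling_rate=250.0,
    )


def gaussian_cluster_features(n_per_class=30, dim=4, sep=6.0, seed=0):
    """Two well-separated Gaussian clusters with +1/-1 labels."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(0.0, 1.0, (n_per_class, dim)) + sep / 2.0
    neg = rng.normal(0.0, 1.0, (n_per_class, dim)) - sep / 2.0
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n_per_class), -np.ones(n_per_class)])
    return X, y
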