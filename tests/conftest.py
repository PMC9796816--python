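import numpy as np
import pytest

from catdecode import EpochsSet, SynthEEGConfig, simulate_group


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_epochs():
    """Hand-constructed 2-trial, 2-channel, 3-sample epochs."""
    return EpochsSet(
        data=np.array([[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
                       [[-1.0, 0.5, 2.5], [0.0, 0.0, 1.0]]]),
        labels=np.array([0, 1]),
        times=np.array([0.0, 2.0, 4.0]),
        srate=500.0,
        channel_positions=np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]),
        participant_id="toy",
        group_tag="test",
    )


def noiseless_epochs(n_per_cat=4, n_channels=3, n_times=5, k=3, scale=1.0):
    """Distinct constant category patterns with zero noise."""
    rng = np.random.default_rng(7)
    patterns = rng.standard_normal((k, n_channels)) * scale
    labels = np.repeat(np.arange(k), n_per_cat)
    data = np.repeat(patterns[labels][:, :, None], n_times, axis=2)
    times = np.arange(n_times) * 20.0
    return EpochsSet(data=data, labels=labels, times=times, srate=50.0)


@pytest.fixture
def small_group():
    """Four tiny synthetic participants with clear signal."""
    cfg = SynthEEGConfig(
        n_participants=4, n_channels=10, srate=100.0,
        epoch_window=(-200.0, 800.0), n_trials_per_category=16,
        snr=2.0, seed=11,
    )
    return cfg, simulate_group(cfg)
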