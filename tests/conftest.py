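import numpy as np
import pytest

from freqtag import EpochSet, SimulationConfig, StimulusSpec

EPOCH_DUR = 14.08
FS = 100.0


@pytest.fixture(scope="session")
def default_spec() -> StimulusSpec:
    return StimulusSpec()


@pytest.fixture(scope="session")
def small_spec() -> StimulusSpec:
    """Few trials — keeps simulation-backed tests fast."""
    return StimulusSpec(n_trials=8, n_outlier_trials=2)


@pytest.fixture(scope="session")
def small_sim() -> SimulationConfig:
    return SimulationConfig(n_subjects=3, n_channels=32, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_epochs(
    data: np.ndarray, fs: float = FS, condition: str = "sentence"
) -> EpochSet:
    return EpochSet(
        data=data,
        fs=fs,
        epoch_duration=data.shape[-1] / fs,
        condition=condition,
        subject_id="S00",
    )


@pytest.fixture()
def noise_epochs(rng) -> EpochSet:
    """22 trials x 4 channels of white noise at the standard epoch length."""
    n = int(FS * EPOCH_DUR)
    return make_epochs(rng.standard_normal((22, 4, n)))
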