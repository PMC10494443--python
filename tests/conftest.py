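import numpy as np
import pytest

from somnoscore import (
    CNNConfig,
    Hypnogram,
    Recording,
    SyntheticSpec,
    build_cnn,
    epoch_signal,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(n_epochs=60, seed=123)


@pytest.fixture(scope="session")
def small_dataset(default_spec):
    """One short synthetic recording, epoched."""
    rec, hyp = generate_dataset(default_spec)
    return epoch_signal(rec, hyp)


@pytest.fixture(scope="session")
def small_pair(default_spec):
    return generate_dataset(default_spec)


@pytest.fixture(scope="session")
def cnn100():
    """An untrained (but fixed-weight) CNN at fs=100."""
    return build_cnn(CNNConfig(fs=100), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_recording(labels, fs=100, seed=0):
    """Recording whose epoch t is the constant value t (easy to trace)."""
    spe = 30 * fs
    samples = np.concatenate([np.full(spe, float(t)) for t in range(len(labels))])
    return (
        Recording(samples, fs=fs, subject_id="toy"),
        Hypnogram(np.asarray(labels, dtype=object), scheme="AASM"),
    )
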