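import numpy as np
import pytest

from semgss.conditioning import preprocess_recording
from semgss.features import ExtractorSpec, featurize_dataset
from semgss.spectrogram import SpectrogramParams
from semgss.synthetic import NoiseSpec, default_class_specs, generate_dataset, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Thirty 3-class recordings with full contamination (10 per class)."""
    specs = default_class_specs(3)
    return generate_dataset(specs, 10, NoiseSpec(), seed=11)


@pytest.fixture(scope="session")
def small_conditioned(small_dataset):
    return [preprocess_recording(r) for r in small_dataset]


@pytest.fixture(scope="session")
def small_bundles(small_conditioned):
    return featurize_dataset(small_conditioned, SpectrogramParams(), ExtractorSpec(seed=7))


@pytest.fixture(scope="session")
def one_recording():
    """One clean-ish 6-channel, 2 s sample of class 0."""
    spec = default_class_specs(3)[0]
    return generate_sample(spec, NoiseSpec(), seed=5)
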