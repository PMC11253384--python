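import numpy as np
import pytest

from diaphmon.synthetic import BreathPhenotype, simulate_breath_train


@pytest.fixture
def clean_phenotype():
    """Noise-free, artifact-free regular breathing at 15/min, 1.2 cm."""
    return BreathPhenotype(
        mean_exdi=1.2, exdi_cv=0.0, mean_rr=15, rr_cv=0.0,
        pdi_noise_sd=0.0, artifact_rate=0.0,
    )


@pytest.fixture
def clean_train(clean_phenotype):
    """80 s noise-free train: 20 breaths of identical shape."""
    return simulate_breath_train(clean_phenotype, duration=80, fs=200, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
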