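import numpy as np
import pytest

from prmquant import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def table1_design():
    """The published dilution-series topology: 11 samples, 19 runs."""
    return sd.generate_design()


@pytest.fixture
def small_truth():
    return sd.generate_truth(8, seed=42)


@pytest.fixture
def noise_free_truth():
    return sd.generate_truth(
        8, seed=42, tech_cv=0.0, bio_cv=0.0, bleed_range=(0.0, 0.0)
    )
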