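import numpy as np
import pytest

from pafburden.synthetic import SimConfig


@pytest.fixture
def tiny_config() -> SimConfig:
    """A small synthetic world for fast end-to-end runs."""
    return SimConfig(
        seed=7,
        n_regions=3,
        n_countries_per_region=2,
        n_draws=50,
        n_studies_per_disease=5,
        n_instruments=10,
        survey_free_regions=("latin_america_and_caribbean",),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
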