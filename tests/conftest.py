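import numpy as np
import pandas as pd
import pytest

from serscal.dataset import SpectrumSet
from serscal.synthdata import GeneratorConfig


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture()
def noise_free_config() -> GeneratorConfig:
    return GeneratorConfig(additive_noise_sd=0.0, multiplicative_jitter_sd=0.0)


@pytest.fixture()
def two_channel_set() -> SpectrumSet:
    """A minimal hand-checkable container: two channels, three spectra."""
    return SpectrumSet(
        wavenumbers=np.array([100.0, 200.0]),
        intensities=np.array([[3.0, 4.0], [0.0, 2.0], [2.0, 0.0]]),
        metadata=pd.DataFrame(
            {
                "spectrum_id": ["a", "b", "c"],
                "group": ["g1", "g2", "g2"],
                "time_h": [0.0, 0.0, 0.0],
                "gh_ng_ml": [0.0, 1.0, 1.0],
                "te_ng_ml": [0.0, 0.0, 0.0],
            }
        ),
    )
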