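import numpy as np
import pytest

from mutseg.simulate import SimulationConfig, simulate_cohort
from mutseg.transcripts import synthetic_gata3_transcript


@pytest.fixture(scope="session")
def gata3():
    return synthetic_gata3_transcript()


@pytest.fixture(scope="session")
def sim_default():
    """One shared default-condition cohort (60 patients, 5 response + 95 null)."""
    config = SimulationConfig(seed=11)
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
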