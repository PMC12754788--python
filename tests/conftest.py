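import numpy as np
import pytest

from tobitgwas.simulate import SimulationScenario, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def censored_dataset():
    """A medium-size dataset with a real effect and 40% censoring."""
    sc = SimulationScenario(
        n_individuals=3000, maf=0.3, effect_size=0.15,
        censored_proportion=0.4, seed=424242,
    )
    return simulate_dataset(sc, 0)
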