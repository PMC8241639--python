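import numpy as np
import pytest

from germfire import SamplerConfig, scenario_library, simulate_species


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def quick_sampler():
    """Short protocol for unit tests; large enough for stable summaries."""
    return SamplerConfig(chains=3, iterations=3000, burn_in=1500, thinning=1, seed=11)


@pytest.fixture
def fd_observations():
    return simulate_species(scenario_library()["fd_geosporous"], seed=7)


@pytest.fixture
def fi_separated_observations():
    return simulate_species(scenario_library()["fi_separated"], seed=1)
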