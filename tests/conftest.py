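import numpy as np
import pytest

from speciesdelim import CladeScenario, separated_scenario, simulate_clade


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_clade():
    """Two well-separated species, modest panel: fast shared fixture."""
    scenario = separated_scenario(
        n_species=2, n_per_species=30, n_traits=4, n_loci=300, divergence=0.3, seed=11
    )
    return simulate_clade(scenario)


@pytest.fixture(scope="session")
def two_group_scores(  ):
    """1-D bimodal + pure-noise axis, used by selection tests."""
    rng = np.random.default_rng(5)
    signal = np.concatenate([rng.normal(-4, 1, 150), rng.normal(4, 1, 150)])
    noise = rng.normal(0, 1, 300)
    return np.column_stack([signal, noise])
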