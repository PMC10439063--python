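import numpy as np
import pytest

from latentnorm import SimulationDesign, make_pattern, simulate_crossed, simulate_items_only


@pytest.fixture(scope="session")
def edge_pattern():
    return make_pattern("edge-biased")


@pytest.fixture(scope="session")
def equidistant_pattern():
    return make_pattern("equidistant")


@pytest.fixture(scope="session")
def items_only_trials():
    """50 items x 25 ratings, edge-biased, unit item/residual SDs."""
    design = SimulationDesign(n_items=50, ratings_per_item=25, seed=1234)
    return simulate_items_only(design, pattern="edge-biased")


@pytest.fixture(scope="session")
def crossed_trials():
    """40 items x 40 participants, 25 ratings each, edge-biased."""
    design = SimulationDesign(
        n_items=40, n_participants=40, ratings_per_item=25,
        items_per_participant=25, seed=1234,
    )
    return simulate_crossed(design, pattern="edge-biased")


@pytest.fixture(scope="session")
def small_single_factor_trials():
    """10 items x 10 ratings with all five categories observed."""
    design = SimulationDesign(n_items=10, ratings_per_item=10, seed=52)
    trials = simulate_items_only(design, pattern="edge-biased")
    assert trials["response"].nunique() == 5
    return trials


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
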