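import numpy as np
import pytest

import endonet as en
from endonet.boolean import boolean_weights, enumerate_fixed_points
from endonet.state_matching import annotate_pancreas_atlas, catalog_from_atlas


@pytest.fixture(scope="session")
def pancreas():
    return en.pancreas_network()


@pytest.fixture(scope="session")
def atlas(pancreas):
    """Equilibrium atlas of the canonical pancreas network at n = 4."""
    return en.find_equilibria(pancreas, en.HillParams(n=4))


@pytest.fixture(scope="session")
def graph(pancreas, atlas):
    return en.build_landscape_graph(pancreas, atlas)


@pytest.fixture(scope="session")
def fixed_points(pancreas):
    return enumerate_fixed_points(boolean_weights(pancreas))


@pytest.fixture(scope="session")
def catalog(atlas):
    return catalog_from_atlas(atlas)


@pytest.fixture(scope="session")
def cell_types(atlas, graph):
    """Pancreatic cell-type name -> atlas label."""
    return annotate_pancreas_atlas(atlas, graph=graph)


@pytest.fixture(scope="session")
def toy():
    from endonet.synthetic import generate_toy_networks

    return generate_toy_networks()


@pytest.fixture(scope="session")
def toy_atlas(toy):
    return en.find_equilibria(toy["self_activator"].network, en.HillParams(n=4))
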