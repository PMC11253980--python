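import numpy as np
import pytest

from neuroslice import (TopologyConfig, GENOTYPES, generate_network,
                        DynamicsConfig, simulate)
from neuroslice.fixtures import make_toy_network


@pytest.fixture(scope="session")
def small_wt_net():
    """A small but non-trivial WT slice network (N=60, 300 μm box)."""
    cfg = TopologyConfig(N=60, L=300.0)
    return generate_network(cfg, GENOTYPES["WT"], seed=11), cfg


@pytest.fixture(scope="session")
def toy_cycle():
    return make_toy_network(3, "cycle")


@pytest.fixture(scope="session")
def tiny_sim_net():
    """100-neuron random weighted digraph for dynamics tests."""
    return make_toy_network(100, "random", weight=3, p=0.1, seed=5)


@pytest.fixture(scope="session")
def tiny_sim_raster(tiny_sim_net):
    cfg = DynamicsConfig(lambda_ext=5.0, t_total=1500.0, t_transient=500.0)
    return simulate(tiny_sim_net, cfg, seed=2)
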