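import numpy as np
import pytest

from pghs1net import (
    NetworkPolicy,
    ParameterSet,
    SimulationConfig,
    build_network,
    simulate,
)


@pytest.fixture(scope="session")
def params():
    return ParameterSet.default()


@pytest.fixture(scope="session")
def model(params):
    return build_network(params=params)


@pytest.fixture(scope="session")
def paper_model(params):
    return build_network(params=params, policy=NetworkPolicy.PAPER_ENUMERATED)


@pytest.fixture(scope="session")
def flux_analysis_traj(model):
    """35 nM enzyme, 80 uM AA, 100 uM cosubstrate: the flux-analysis condition."""
    cfg = SimulationConfig(enzyme_total=0.035, aa0=80.0, rc0=100.0, t_end=300.0)
    return simulate(model, cfg)


@pytest.fixture(scope="session")
def long_traj(model):
    """High-cosubstrate run long enough for full self-inactivation."""
    cfg = SimulationConfig(enzyme_total=0.035, aa0=80.0, rc0=1000.0, t_end=1200.0)
    return simulate(model, cfg)
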