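import numpy as np
import pytest

from esbbn.fixtures import build_reference_network, catchment_path, load_reference_network
from esbbn.network import CPT, NetworkDefinition, NodeSpec
from esbbn.scenario import load_catchment


@pytest.fixture(scope="session")
def toy_net() -> NetworkDefinition:
    """Two-node chain A -> B with known hand-computable posteriors."""
    a = NodeSpec("A", ("H", "L"))
    b = NodeSpec("B", ("G", "P"))
    cpt = CPT.from_rows(
        "B", ["A"], b.states, [a.states], {("H",): [0.9, 0.1], ("L",): [0.2, 0.8]}
    )
    return NetworkDefinition(
        nodes=[a, b], edges=[("A", "B")], cpts={"B": cpt}, priors={"A": np.array([0.6, 0.4])}
    )


@pytest.fixture(scope="session")
def ref_net() -> NetworkDefinition:
    """The shipped reference network, loaded from its definition file."""
    return load_reference_network()


@pytest.fixture(scope="session")
def ref_net_built() -> NetworkDefinition:
    """The same network rebuilt in memory (file/builder must agree)."""
    return build_reference_network()


@pytest.fixture(scope="session")
def suir():
    return load_catchment(catchment_path("suir"))


@pytest.fixture(scope="session")
def dodder():
    return load_catchment(catchment_path("dodder"))


@pytest.fixture(scope="session")
def moy():
    return load_catchment(catchment_path("moy"))
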