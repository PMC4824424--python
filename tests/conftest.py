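import pytest

from oglyco.simulator import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_network():
    """Default panel, six iterations — a few hundred structures."""
    return simulate(SimulationConfig(max_iterations=6))


@pytest.fixture(scope="session")
def glycan_pool(small_network):
    """Canonical identifiers reachable by the enzyme panel (no bare site)."""
    return small_network.glycans()


@pytest.fixture(scope="session")
def full_8930_network():
    """The headline forward run: all 25 enzymes, no GlcNAc cap.

    Nine engine iterations from the bare site correspond to the published
    count of eight iterations starting at the Tn antigen.
    """
    return simulate(SimulationConfig(max_iterations=9))
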