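import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from actinet.netmodel import (  # noqa: E402
    ACTIVATION,
    INHIBITION,
    Network,
    S1_REACTANT,
    S2_REACTANT_SUBSTRATE,
)


@pytest.fixture
def two_node() -> Network:
    """Constant source A (fully active) -> B, S2 activation, u = 0."""
    return (
        Network(time_unit="tu")
        .add_node("A", levels=100, initial_level=100)
        .add_node("B", levels=100, initial_level=0)
        .add_interaction("A", "B", ACTIVATION, S2_REACTANT_SUBSTRATE, k=0.5, uncertainty=0.0, id="A->B")
    )


@pytest.fixture
def ramp_network() -> Network:
    """S1 activation at a = 1, k = 0.1, L = 10, u = 0: one step per time unit."""
    return (
        Network(time_unit="tu")
        .add_node("A", levels=10, initial_level=10)
        .add_node("B", levels=10, initial_level=0)
        .add_interaction("A", "B", ACTIVATION, S1_REACTANT, k=0.1, uncertainty=0.0, id="A->B")
    )
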