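import hypothesis
import pytest

from wormdev.config import SpatialConfig
from wormdev.connectome import Connection, Connectome, Neuron, lift_to_3d

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_neuron(
    nid,
    birth,
    ap=0.0,
    dv=0.0,
    side="midline",
    config=None,
    **kw,
):
    config = config or SpatialConfig()
    return Neuron(
        id=nid,
        position2d=(ap, dv),
        side=side,
        birth_time=birth,
        position3d=lift_to_3d((ap, dv), side, config),
        **kw,
    )


def make_connectome(neuron_specs, edge_specs, config=None, **kw):
    """neuron_specs: (id, birth[, kwargs]); edge_specs: (pre, post[, kind, directedness])."""
    config = config or SpatialConfig()
    neurons = []
    for spec in neuron_specs:
        nid, birth, *rest = spec
        neurons.append(make_neuron(nid, birth, config=config, **(rest[0] if rest else {})))
    conns = [Connection(*spec) for spec in edge_specs]
    return Connectome(neurons, conns, config=config, **kw)


@pytest.fixture
def triangle_connectome():
    """Three mutually connected neurons born at 100, 150, 400 minutes."""
    return make_connectome(
        [("A", 100.0), ("B", 150.0), ("C", 400.0)],
        [("A", "B"), ("B", "C"), ("A", "C")],
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-parameter synthetic connectome shared across tests."""
    from wormdev.synthetic import generate_connectome

    connectome, truth = generate_connectome()
    return connectome, truth
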