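import numpy as np
import pytest

from syncytia.compartment_model import (
    CompartmentGraph,
    Edge,
    Node,
    PhotoProtocol,
    make_fixture,
)


@pytest.fixture(scope="session")
def two_open_movie():
    return make_fixture("two_open", seed=7)


@pytest.fixture(scope="session")
def two_closed_movie():
    return make_fixture("two_closed", seed=7)


@pytest.fixture(scope="session")
def chain3_movie():
    return make_fixture("chain3", seed=7)


@pytest.fixture
def two_node_graph():
    def _make(k: float, species=("green",)):
        return CompartmentGraph(
            nodes=[Node("n1", {s: 1.0 for s in species}), Node("n2", {s: 1.0 for s in species})],
            edges=[Edge("n1", "n2", k)],
            species=list(species),
        )

    return _make


@pytest.fixture
def bleach_protocol():
    def _make(beta: float, frames: int = 60, interval: float = 5.0, decay: float = 0.0):
        return PhotoProtocol(
            pre_frames=0,
            event_frames=frames,
            post_frames=1,
            frame_interval=interval,
            event_kind="bleach",
            target_node="n1",
            event_rate=beta,
            species="green",
            imaging_decay=decay,
        )

    return _make
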