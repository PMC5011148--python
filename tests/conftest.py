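import numpy as np
import pytest

from himnet.graph import Graph, MultiplexSeries, MultiplexSnapshot, graph_from_edges


def random_binary_graph(n: int, p: float, rng: np.random.Generator) -> Graph:
    a = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(iu.size) < p
    a[iu[hit], ju[hit]] = 1.0
    return Graph(a + a.T)


def random_weighted_graph(n: int, rng: np.random.Generator) -> Graph:
    a = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    a[iu, ju] = rng.random(iu.size)
    return Graph(a + a.T)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def path3():
    """Path a-b-c on three nodes."""
    return graph_from_edges(3, [(0, 1), (1, 2)], ("a", "b", "c"))


@pytest.fixture
def toy_series():
    """A 3-step, 2-layer multiplex on 4 nodes with known evolution."""
    l1 = [
        graph_from_edges(4, [(0, 1), (2, 3)]),
        graph_from_edges(4, [(0, 1), (2, 3)]),
        graph_from_edges(4, [(0, 1), (1, 2), (2, 3)]),
    ]
    l2 = [
        graph_from_edges(4, [(0, 2)]),
        graph_from_edges(4, [(0, 2), (1, 3)]),
        graph_from_edges(4, [(0, 2), (1, 3)]),
    ]
    snaps = tuple(
        MultiplexSnapshot((a, b), ("alpha", "beta")) for a, b in zip(l1, l2)
    )
    return MultiplexSeries(snaps)


@pytest.fixture(scope="session")
def keds_fixture(tmp_path_factory):
    """A small synthetic KEDS-style event file with known counts.

    Synthetic stand-in for a deposited event-data file; written
    programmatically so the counts asserted in tests are true by
    construction: 3 months (Jan-Mar 1991), actors IRQ/USA/IRN/UNO/KUW.
    """
    lines = [
        "# synthetic event data fixture",
        "910115 IRQ USA 102",
        "910117 USA IRQ 121",  # same dyad, other direction, other layer
        "910120 IRN IRQ 223",
        "910121 IRQ IRN 223",  # duplicate dyad+code+month -> one link
        "910205 IRQ UNO 031",
        "910211 UNO IRQ 031",
        "910215 KUW USA 042",
        "910301 IRQ USA 223",
        "910302 IRQ USA 223",
        "910303 IRQ USA 223",
        "910310 IRN USA 121",
        "bad line without fields",
        "910311 IRQ USA 999",  # unmonitored code -> skipped
    ]
    path = tmp_path_factory.mktemp("keds") / "synthetic_events.txt"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return str(path)
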