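import numpy as np
import pytest

from pathspace import GeneList, PathwayGraph
from pathspace.synthetic import toy_fig1


def make_graph(names, name_edges, layout=None, signal=None):
    """Assemble a PathwayGraph from name-labelled edges (test helper)."""
    lut = {v: i for i, v in enumerate(names)}
    edges = frozenset(
        (lut[a], lut[b]) if lut[a] < lut[b] else (lut[b], lut[a]) for a, b in name_edges
    )
    if layout is None:
        # deterministic placeholder layout on a circle
        t = 2 * np.pi * np.arange(len(names)) / max(1, len(names))
        layout = 0.5 + 0.4 * np.column_stack([np.cos(t), np.sin(t)])
    return PathwayGraph(tuple(names), edges, np.asarray(layout, float), signal)


def floyd_warshall(g: PathwayGraph) -> np.ndarray:
    """Independent all-pairs hop-count oracle (dense triple loop)."""
    n = g.n_vertices
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in g.edges:
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def nn_oracle(d: np.ndarray, fi, ti) -> float:
    """Double-loop mean-of-minima oracle for the directed statistic."""
    mins = []
    for i in fi:
        best = min(d[i, j] for j in ti)
        if np.isfinite(best):
            mins.append(best)
    return sum(mins) / len(mins)


def random_graph(rng: np.random.Generator, n: int, p: float = 0.3) -> PathwayGraph:
    """Erdős–Rényi-style random test graph with names V00..."""
    names = [f"V{i:02d}" for i in range(n)]
    edges = [
        (names[i], names[j]) for i in range(n) for j in range(i + 1, n)
        if rng.random() < p
    ]
    return make_graph(names, edges)


@pytest.fixture(scope="session")
def toy():
    return toy_fig1()


@pytest.fixture
def path_abc():
    """Path graph A - B - C."""
    return make_graph(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def glist():
    return lambda *ids, label="": GeneList(tuple(ids), label)
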