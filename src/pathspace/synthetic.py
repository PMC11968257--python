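"""Synthetic fixtures and simulators.

Everything here is a pure function of its arguments (seed included):
identical inputs give bitwise-identical graphs, layouts and lists. The
module provides a hand-encoded toy pathway space with two gene lists whose
first-nearest-neighbor distance is a known worked value, a scale-free-like
random pathway-space generator, and gene-list samplers — uniform draws for
null behavior and neighborhood (BFS-ball) draws for planted proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphspace import GeneList, PathwayGraph, normalize_layout

__all__ = ["ToyFixture", "toy_fig1", "random_space", "sample_lists"]


@dataclass(frozen=True)
class ToyFixture:
    graph: PathwayGraph
    L1: GeneList
    L2: GeneList


# Toy pathway space: two 4-gene lists (A* in L1, B* in L2) bridged by
# connector genes C*. Per-gene hop minima to the other list are (1, 1, 1, 2)
# in BOTH directions, so the average first-nearest-neighbor path distance is
# 1.25 whichever direction convention is used.
_TOY_NAMES = ("A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4", "C1", "C2", "C3")
_TOY_EDGES = (
    ("A1", "A2"), ("A2", "A3"), ("A3", "A4"),   # L1 cluster chain
    ("B2", "B3"),                               # L2 cluster link
    ("A1", "B1"), ("A3", "B1"), ("A2", "B2"), ("A1", "B4"),  # direct bridges
    ("A4", "C1"), ("C1", "B3"),                 # two-step bridge
    ("A2", "C2"), ("B4", "C3"),                 # peripheral connectors
)
_TOY_XY = {
    "A1": (0.30, 0.55), "A2": (0.20, 0.40), "A3": (0.25, 0.22), "A4": (0.12, 0.10),
    "B1": (0.55, 0.45), "B2": (0.62, 0.68), "B3": (0.75, 0.50), "B4": (0.58, 0.80),
    "C1": (0.45, 0.15), "C2": (0.05, 0.60), "C3": (0.80, 0.88),
}


def toy_fig1() -> ToyFixture:
    """The schematic toy pathway space with gene lists L1 and L2.

    Encodes a small two-cluster graph in which the average path distance to
    first nearest neighbors between L1 = {A1..A4} and L2 = {B1..B4} is 1.25
    (three genes one hop away, one gene two hops away, in each direction).
    The encoding is data; the worked value is asserted by tests rather than
    trusted.
    """
    lut = {v: i for i, v in enumerate(_TOY_NAMES)}
    edges = frozenset(
        (lut[a], lut[b]) if lut[a] < lut[b] else (lut[b], lut[a]) for a, b in _TOY_EDGES
    )
    layout = normalize_layout(np.array([_TOY_XY[v] for v in _TOY_NAMES]))
    graph = PathwayGraph(_TOY_NAMES, edges, layout)
    return ToyFixture(
        graph=graph,
        L1=GeneList(("A1", "A2", "A3", "A4"), "L1"),
        L2=GeneList(("B1", "B2", "B3", "B4"), "L2"),
    )


def _vertex_names(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"G{i + 1:0{width}d}" for i in range(n))


def random_space(n_vertices: int, attach_edges: int = 2, seed: int = 0) -> PathwayGraph:
    """Random connected pathway space with a heavy-tailed degree distribution.

    Grows a preferential-attachment (Barabási–Albert) graph of ``n_vertices``
    vertices, each new vertex attaching ``attach_edges`` edges — a standard
    stand-in for interactome-like topology. Vertices get synthetic symbols
    G0001, G0002, ...; the layout is a seeded force-directed (Fruchterman–
    Reingold) embedding normalized to the unit square.
    """
    if n_vertices < 3:
        raise ValueError("n_vertices must be >= 3")
    if attach_edges < 1:
        raise ValueError("attach_edges must be >= 1")
    g = nx.barabasi_albert_graph(n_vertices, attach_edges, seed=seed)
    pos = nx.spring_layout(g, seed=seed)
    names = _vertex_names(n_vertices)
    edges = frozenset((i, j) if i < j else (j, i) for i, j in g.edges())
    layout = normalize_layout(np.array([pos[i] for i in range(n_vertices)]))
    return PathwayGraph(names, edges, layout)


def sample_lists(
    g: PathwayGraph,
    size: int,
    mode: str = "uniform",
    seed: int = 0,
    label: str = "",
    center: str | None = None,
) -> GeneList:
    """Draw a gene list from the graph.

    ``uniform``: a without-replacement uniform vertex sample — the null
    model's notion of a random gene list. ``neighborhood``: the BFS ball
    around a center vertex (random unless ``center`` names one), truncated to
    ``size`` — lists with planted spatial coherence, used to demonstrate
    power. Within each BFS level the expansion order is shuffled by the
    seeded generator, so two draws around the same center with different
    seeds give overlapping but distinct lists. Pure function of its
    arguments: identical inputs give identical lists.
    """
    n = g.n_vertices
    if not 1 <= size <= n:
        raise ValueError(f"size must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        idx = rng.choice(n, size=size, replace=False)
    elif mode == "neighborhood":
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, j in g.edges:
            adj[i].append(j)
            adj[j].append(i)
        c = int(g.index_of([center])[0]) if center is not None else int(rng.integers(n))
        seen = {c}
        order = [c]
        frontier = [c]
        while frontier and len(order) < size:
            level: list[int] = []
            for v in frontier:
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        level.append(w)
            rng.shuffle(level)
            order.extend(level)
            frontier = level
        if len(order) < size:
            raise ValueError(
                f"neighborhood of vertex {c} has only {len(order)} reachable "
                f"vertices, need {size}"
            )
        idx = np.array(order[:size])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GeneList(tuple(g.vertex_names[i] for i in idx), label or f"{mode}{size}")
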