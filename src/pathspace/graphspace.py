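"""Data model and I/O for the pathway-space graph and gene lists.

A *pathway space* is a large undirected gene-interaction graph shipped with a
fixed 2D layout, in which gene sets can be visualized and compared spatially.
This module holds the in-memory containers (:class:`PathwayGraph`,
:class:`GeneList`), readers/writers for GraphML and edge-list/layout TSV,
gene-list readers (two-column CSV and MSigDB GMT), and the basic queries the
protocol needs: hub extraction, membership validation, list/graph
intersection, and per-vertex signal assignment.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "GeneList",
    "load_graph",
    "write_graph",
    "top_hubs",
    "set_signal",
    "validate_membership",
    "intersect_with_graph",
    "read_gene_lists_csv",
    "read_gmt",
    "normalize_layout",
]


class GraphFormatError(ValueError):
    """Raised when an input graph or gene-list file violates the contract."""


@dataclass(frozen=True)
class GeneList:
    """An ordered, de-duplicated, non-empty collection of gene symbols.

    Parameters
    ----------
    ids
        Gene symbols, in order. Duplicates are rejected at construction;
        use :meth:`from_iterable` to deduplicate with a warning instead.
    label
        Display label, e.g. ``"L1"``.
    """

    ids: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise ValueError(f"gene list {self.label!r} is empty")
        if any((not isinstance(g, str)) or g == "" for g in self.ids):
            raise ValueError(f"gene list {self.label!r} contains empty/non-string ids")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dups = sorted({g for g in self.ids if g in seen or seen.add(g)})
            raise ValueError(f"gene list {self.label!r} has duplicate ids: {dups}")

    @classmethod
    def from_iterable(cls, ids: Iterable[str], label: str = "") -> "GeneList":
        """Build a list, silently-with-warning dropping later duplicates."""
        out: list[str] = []
        seen: set[str] = set()
        ndup = 0
        for g in ids:
            if g in seen:
                ndup += 1
                continue
            seen.add(g)
            out.append(g)
        if ndup:
            logger.warning("gene list %r: dropped %d duplicate id(s)", label, ndup)
        return cls(tuple(out), label)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, g: object) -> bool:
        return g in self.ids


@dataclass(frozen=True)
class PathwayGraph:
    """Undirected gene-interaction graph with names, 2D layout and signal.

    Attributes
    ----------
    vertex_names
        Unique, non-empty gene symbols; index order is the canonical vertex
        order for ``layout``, ``signal`` and distance matrices.
    edges
        Unordered pairs of vertex indices, stored as sorted ``(i, j)`` tuples
        with ``i < j``. No self-loops, no duplicates.
    layout
        ``(n, 2)`` float array of per-vertex coordinates, normalized to the
        unit square on load (aspect-preserving).
    signal
        Per-vertex real value; defaults to all zeros.
    """

    vertex_names: tuple[str, ...]
    edges: frozenset[tuple[int, int]]
    layout: np.ndarray
    signal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.vertex_names)
        if n == 0:
            raise ValueError("graph must have at least one vertex")
        if any((not isinstance(v, str)) or v == "" for v in self.vertex_names):
            raise ValueError("vertex names must be non-empty strings")
        if len(set(self.vertex_names)) != n:
            seen: set[str] = set()
            dups = sorted({v for v in self.vertex_names if v in seen or seen.add(v)})
            raise GraphFormatError(f"duplicate vertex names: {dups}")
        for i, j in self.edges:
            if not (0 <= i < j < n):
                raise ValueError(f"invalid edge ({i}, {j}) for {n} vertices")
        layout = np.asarray(self.layout, dtype=float)
        if layout.shape != (n, 2):
            raise ValueError(f"layout must be ({n}, 2), got {layout.shape}")
        if not np.all(np.isfinite(layout)):
            raise ValueError("layout coordinates must be finite")
        object.__setattr__(self, "layout", layout)
        sig = self.signal
        if sig is None:
            sig = np.zeros(n)
        sig = np.asarray(sig, dtype=float)
        if sig.shape != (n,):
            raise ValueError(f"signal must have shape ({n},), got {sig.shape}")
        object.__setattr__(self, "signal", sig)

    # -- basic queries -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, names: Iterable[str]) -> np.ndarray:
        """Map gene symbols to vertex indices (case-sensitive; KeyError on miss)."""
        lut = self._name_index()
        return np.array([lut[g] for g in names], dtype=int)

    def _name_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.vertex_names)}

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, name in enumerate(self.vertex_names):
            g.add_node(name, x=float(self.layout[i, 0]), y=float(self.layout[i, 1]),
                       signal=float(self.signal[i]))
        g.add_edges_from(
            (self.vertex_names[i], self.vertex_names[j]) for i, j in self.edges
        )
        return g


def normalize_layout(coords: np.ndarray) -> np.ndarray:
    """Affine-map coordinates into the unit square, preserving aspect ratio.

    The longer axis spans [0, 1]; the shorter axis is centered. A layout with
    zero extent (single vertex, or all coincident) maps to (0.5, 0.5).
    """
    coords = np.asarray(coords, dtype=float)
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    scale = span.max()
    if scale == 0:
        return np.full_like(coords, 0.5)
    out = (coords - lo) / scale
    # center the shorter dimension
    out += (1.0 - span / scale) / 2.0
    return out


def _build(
    names: Sequence[str],
    name_pairs: Iterable[tuple[str, str]],
    layout: np.ndarray,
    signal: np.ndarray | None = None,
    *,
    normalize: bool = True,
) -> PathwayGraph:
    """Assemble a PathwayGraph from name-labelled edges, applying hygiene rules.

    Self-loops and duplicate edges are dropped with a logged count; an edge
    endpoint missing from ``names`` is fatal.
    """
    lut = {v: i for i, v in enumerate(names)}
    edges: set[tuple[int, int]] = set()
    n_loops = n_dups = 0
    for a, b in name_pairs:
        if a not in lut or b not in lut:
            missing = [v for v in (a, b) if v not in lut]
            raise GraphFormatError(f"edge endpoint(s) missing from vertex set: {missing}")
        if a == b:
            n_loops += 1
            continue
        e = (lut[a], lut[b]) if lut[a] < lut[b] else (lut[b], lut[a])
        if e in edges:
            n_dups += 1
        else:
            edges.add(e)
    if n_loops:
        logger.warning("dropped %d self-loop(s) at load", n_loops)
    if n_dups:
        logger.warning("dropped %d duplicate edge(s) at load", n_dups)
    layout = np.asarray(layout, dtype=float)
    if normalize:
        layout = normalize_layout(layout)
    return PathwayGraph(tuple(names), frozenset(edges), layout, signal)


def load_graph(path: str | Path, format: str | None = None) -> PathwayGraph:
    """Load a pathway-space graph from GraphML or edge-list+layout TSV.

    Parameters
    ----------
    path
        GraphML file, or for the TSV dialect the *edge-list* file; the layout
        file is then ``<stem>.layout.tsv`` next to it, or pass a tuple via
        :func:`load_edgelist`.
    format
        ``"graphml"`` or ``"edgelist"``; inferred from the suffix if omitted.

    Vertex attributes ``name``, ``x``, ``y`` are required in GraphML (``name``
    falls back to the node id). Layout is normalized to the unit square.
    Self-loops and duplicate edges are dropped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() in {".graphml", ".xml"} else "edgelist"
    if format == "graphml":
        return _load_graphml(path)
    if format == "edgelist":
        layout_path = path.with_suffix("").with_suffix("")  # strip .tsv
        layout_path = path.parent / (path.name.replace(".edges.tsv", "") + ".layout.tsv") \
            if path.name.endswith(".edges.tsv") else path.with_name(path.stem + ".layout.tsv")
        return load_edgelist(path, layout_path)
    raise ValueError(f"unknown graph format {format!r}")


def _load_graphml(path: Path) -> PathwayGraph:
    g = nx.read_graphml(path)
    if g.is_directed():
        g = g.to_undirected()
    names: list[str] = []
    coords: list[tuple[float, float]] = []
    signal: list[float] = []
    node_to_name: dict[object, str] = {}
    for node, data in g.nodes(data=True):
        name = str(data.get("name", node))
        if name == "":
            raise GraphFormatError(f"node {node!r} has an empty name")
        try:
            x, y = float(data["x"]), float(data["y"])
        except KeyError as exc:
            raise GraphFormatError(f"node {name!r} lacks layout attribute {exc}") from exc
        node_to_name[node] = name
        names.append(name)
        coords.append((x, y))
        signal.append(float(data.get("signal", 0.0)))
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dups = sorted({v for v in names if v in seen or seen.add(v)})
        raise GraphFormatError(f"duplicate vertex names in {path}: {dups}")
    pairs = [(node_to_name[a], node_to_name[b]) for a, b in g.edges()]
    return _build(names, pairs, np.array(coords), np.array(signal))


def load_edgelist(edges_path: str | Path, layout_path: str | Path) -> PathwayGraph:
    """Load from a two-column name TSV (edges) plus a name/x/y TSV (layout).

    Every vertex must appear in the layout file; layout-only vertices are kept
    as isolated vertices. An edge endpoint absent from the layout is fatal.
    """
    edges_path, layout_path = Path(edges_path), Path(layout_path)
    names: list[str] = []
    coords: list[tuple[float, float]] = []
    with open(layout_path, newline="") as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        required = {"name", "x", "y"}
        if rd.fieldnames is None or not required.issubset(rd.fieldnames):
            raise GraphFormatError(
                f"layout TSV {layout_path} must have columns name, x, y "
                f"(got {rd.fieldnames})"
            )
        for row in rd:
            names.append(row["name"])
            coords.append((float(row["x"]), float(row["y"])))
    pairs: list[tuple[str, str]] = []
    with open(edges_path, newline="") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GraphFormatError(f"{edges_path}:{ln}: expected two tab-separated names")
            pairs.append((fields[0], fields[1]))
    return _build(names, pairs, np.array(coords))


def write_graph(g: PathwayGraph, path: str | Path) -> None:
    """Write to GraphML with vertex attributes name, x, y, signal."""
    nx.write_graphml(g.to_networkx(), Path(path))


def top_hubs(g: PathwayGraph, k: int) -> GeneList:
    """Names of the ``k`` highest-degree vertices (hub genes).

    Sort is by decreasing degree; ties are broken lexicographically by vertex
    name so the result is deterministic.
    """
    if not 1 <= k <= g.n_vertices:
        raise ValueError(f"k must be in [1, {g.n_vertices}], got {k}")
    deg = g.degrees()
    order = sorted(range(g.n_vertices), key=lambda i: (-deg[i], g.vertex_names[i]))
    return GeneList(tuple(g.vertex_names[i] for i in order[:k]), label=f"top{k}hubs")


def validate_membership(g: PathwayGraph, genes: GeneList) -> tuple[bool, list[str]]:
    """Check that every gene in the list is a vertex of the graph.

    Returns ``(ok, missing)`` where ``missing`` enumerates absent symbols,
    preserving the list order. Matching is case-sensitive on raw symbols.
    """
    present = set(g.vertex_names)
    missing = [gid for gid in genes.ids if gid not in present]
    return (len(missing) == 0, missing)


def set_signal(
    g: PathwayGraph, genes: GeneList, value: float = 1.0, background: float = 0.0
) -> PathwayGraph:
    """Return a copy of ``g`` with ``signal = value`` on the list, ``background`` elsewhere.

    The background is reset on every call, so successive assignments (e.g. L1
    then L2) never accumulate. Unknown symbols are an error.
    """
    ok, missing = validate_membership(g, genes)
    if not ok:
        raise KeyError(f"gene(s) not in graph: {missing}")
    sig = np.full(g.n_vertices, float(background))
    sig[g.index_of(genes.ids)] = float(value)
    return replace(g, signal=sig)


def intersect_with_graph(genes: GeneList, g: PathwayGraph) -> GeneList:
    """Filter a gene list to the symbols present in the graph, keeping order.

    An empty intersection is an error: the downstream distance statistic is
    undefined on an empty list.
    """
    present = set(g.vertex_names)
    kept = tuple(gid for gid in genes.ids if gid in present)
    if not kept:
        raise ValueError(
            f"gene list {genes.label!r} has no genes in the graph "
            f"({len(genes)} ids checked)"
        )
    return GeneList(kept, genes.label)


def read_gene_lists_csv(path: str | Path) -> dict[str, GeneList]:
    """Read gene lists from a two-column CSV with header columns ID, List.

    Returns one :class:`GeneList` per distinct ``List`` value, keyed and
    labeled by it, in first-appearance order. Duplicate IDs within a list are
    dropped with a warning.
    """
    path = Path(path)
    groups: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        rd = csv.DictReader(fh)
        if rd.fieldnames is None or not {"ID", "List"}.issubset(rd.fieldnames):
            raise GraphFormatError(
                f"{path}: CSV must have header columns ID and List (got {rd.fieldnames})"
            )
        for row in rd:
            groups.setdefault(row["List"], []).append(row["ID"])
    return {lab: GeneList.from_iterable(ids, lab) for lab, ids in groups.items()}


def read_gmt(path: str | Path) -> dict[str, GeneList]:
    """Read gene sets from a GMT file (name TAB description TAB member...).

    The MSigDB dialect: one set per line, the description column is ignored.
    """
    path = Path(path)
    out: dict[str, GeneList] = {}
    with open(path, newline="") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GraphFormatError(
                    f"{path}:{ln}: GMT line needs name, description and >=1 member"
                )
            name, members = fields[0], [m for m in fields[2:] if m]
            out[name] = GeneList.from_iterable(members, name)
    return out
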