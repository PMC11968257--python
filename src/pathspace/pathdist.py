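"""The statistical core: hop-distance matrices, the nearest-neighbor
path-distance statistic, its permutation null, and the hypergeometric
overlap test.

The central question is whether two gene lists sit closer to each other on a
gene-interaction graph than random lists of the same sizes would. For a gene
``v`` in one list, its *first-nearest-neighbor path distance* is the minimum
hop count (unweighted shortest-path edge count) to any gene of the other
list; the statistic averages these minima. A permutation null re-draws both
lists uniformly from all vertices and yields an empirical left-tail p-value
(small distance = proximity) and a z-score that makes results from
differently sized list pairs comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.stats import hypergeom

from .graphspace import GeneList, PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "PathDistanceResult",
    "OverlapTestParams",
    "shortest_path_matrix",
    "shortest_paths_from",
    "nn_path_distance",
    "null_distribution",
    "path_distance_test",
    "hypergeom_upper_tail",
    "read_distance_tsv",
    "write_distance_tsv",
]

Direction = Literal["from_to", "symmetric"]


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs unweighted shortest-path (hop-count) distances.

    ``d[i, j]`` is the minimum number of edges on any path between vertices
    ``i`` and ``j``; ``+inf`` marks pairs in different connected components.
    Symmetric with zero diagonal.
    """

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix must be ({n}, {n}), got {d.shape}")
        object.__setattr__(self, "d", d)

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        lut = {v: i for i, v in enumerate(self.labels)}
        try:
            return np.array([lut[g] for g in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc} not among distance-matrix labels") from exc

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PathDistanceResult:
    """Observed statistic, permutation null and derived inference.

    ``p_value`` uses the add-one empirical estimator
    ``(1 + #{null <= observed}) / (nperm + 1)`` (left tail, so a small
    observed distance is evidence of proximity); ``z_score`` is
    ``(observed - mean(null)) / sd(null)`` and is NaN when the null is
    degenerate (zero spread).
    """

    observed: float
    null_sample: np.ndarray
    p_value: float
    z_score: float
    nperm: int
    seed: int
    from_size: int
    to_size: int
    direction: Direction

    def to_dict(self) -> dict:
        d = asdict(self)
        d["null_sample"] = [float(x) for x in self.null_sample]
        d["schema_version"] = 1
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass(frozen=True)
class OverlapTestParams:
    """Parameters of the one-sided hypergeometric overlap test.

    Mirrors R's ``phyper(q, m, n, k)``: ``q`` observed overlap, ``m`` size of
    the first list, ``n`` universe size minus ``m``, ``k`` size of the second
    list.
    """

    q: int
    m: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.m <= 0 or self.n <= 0 or self.k <= 0:
            raise ValueError("m, n, k must be positive")
        if self.k > self.m + self.n:
            raise ValueError(f"k={self.k} exceeds universe size {self.m + self.n}")
        if not 0 <= self.q <= min(self.m, self.k):
            raise ValueError(f"q={self.q} outside [0, min(m, k)={min(self.m, self.k)}]")


def hypergeom_upper_tail(params: OverlapTestParams) -> float:
    """P(X > q): the strictly-greater hypergeometric tail.

    X counts white balls in ``k`` draws without replacement from an urn of
    ``m`` white and ``n`` black balls — the overlap of two fixed-size lists
    drawn from a finite gene universe. Matches R's
    ``phyper(q, m, n, k, lower.tail = FALSE)``.
    """
    return float(hypergeom.sf(params.q, params.m + params.n, params.m, params.k))


def _adjacency(g: PathwayGraph) -> sparse.csr_matrix:
    n = g.n_vertices
    if not g.edges:
        return sparse.csr_matrix((n, n))
    ij = np.array(sorted(g.edges), dtype=int)
    ones = np.ones(len(ij))
    a = sparse.coo_matrix((ones, (ij[:, 0], ij[:, 1])), shape=(n, n))
    return (a + a.T).tocsr()


def shortest_path_matrix(g: PathwayGraph) -> DistanceMatrix:
    """All-pairs hop counts by BFS from every vertex (unweighted semantics)."""
    d = shortest_path(_adjacency(g), method="D", unweighted=True, directed=False)
    return DistanceMatrix(g.vertex_names, d)


def shortest_paths_from(g: PathwayGraph, sources: GeneList) -> pd.DataFrame:
    """Hop counts from the given source genes to every vertex.

    Row-wise alternative to :func:`shortest_path_matrix` for graphs too large
    to hold a dense all-pairs matrix; returns a sources x vertices DataFrame.
    """
    idx = g.index_of(sources.ids)
    d = shortest_path(_adjacency(g), method="D", unweighted=True, directed=False,
                      indices=idx)
    return pd.DataFrame(d, index=list(sources.ids), columns=list(g.vertex_names))


def _directed_mean_min(sub: np.ndarray, context: str = "") -> float:
    """Mean over rows of the row-minimum, excluding +inf rows with a log."""
    mins = sub.min(axis=1)
    finite = np.isfinite(mins)
    n_inf = int((~finite).sum())
    if n_inf == len(mins):
        raise ValueError("statistic undefined: every from-gene is unreachable from the to-list")
    if n_inf:
        logger.info("nn_path_distance%s: excluded %d unreachable gene(s)", context, n_inf)
    return float(mins[finite].mean())


def nn_path_distance(
    D: DistanceMatrix,
    from_list: GeneList,
    to_list: GeneList,
    direction: Direction = "from_to",
) -> float:
    """Average path distance to first nearest neighbors between two lists.

    ``from_to``: mean over genes ``v`` of the *from* list of
    ``min_w in to d[v, w]``. ``symmetric``: the mean of the two directed
    values. A gene present in both lists is its own nearest neighbor and
    contributes 0. Genes whose minimum is infinite (unreachable component)
    are excluded from the average with a logged count; if every term is
    infinite the statistic is undefined and an error is raised.
    """
    fi = D.index_of(from_list.ids)
    ti = D.index_of(to_list.ids)
    fwd = _directed_mean_min(D.d[np.ix_(fi, ti)], " (from->to)")
    if direction == "from_to":
        return fwd
    if direction == "symmetric":
        rev = _directed_mean_min(D.d[np.ix_(ti, fi)], " (to->from)")
        return 0.5 * (fwd + rev)
    raise ValueError(f"unknown direction {direction!r}")


def _null_stat(d: np.ndarray, fi: np.ndarray, ti: np.ndarray, direction: Direction) -> float:
    sub = d[np.ix_(fi, ti)]
    mins = sub.min(axis=1)
    fwd = mins[np.isfinite(mins)].mean() if np.isfinite(mins).any() else np.nan
    if direction == "from_to":
        return float(fwd)
    mins2 = sub.min(axis=0)
    rev = mins2[np.isfinite(mins2)].mean() if np.isfinite(mins2).any() else np.nan
    return float(0.5 * (fwd + rev))


def null_distribution(
    D: DistanceMatrix,
    from_size: int,
    to_size: int,
    nperm: int,
    seed: int,
    direction: Direction = "from_to",
) -> np.ndarray:
    """Permutation null of the statistic for random same-size list pairs.

    Each of the ``nperm`` replicates draws two independent uniform
    without-replacement vertex samples of the stated sizes from *all* graph
    vertices (no degree matching) and records the statistic. One seeded
    generator drives the whole loop, so the sample is bitwise reproducible.
    """
    n = D.n
    if not (1 <= from_size <= n and 1 <= to_size <= n):
        raise ValueError(f"list sizes must be in [1, {n}]")
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(nperm)
    d = D.d
    for r in range(nperm):
        fi = rng.choice(n, size=from_size, replace=False)
        ti = rng.choice(n, size=to_size, replace=False)
        out[r] = _null_stat(d, fi, ti, direction)
    return out


def path_distance_test(
    D: DistanceMatrix,
    from_list: GeneList,
    to_list: GeneList,
    nperm: int = 10000,
    seed: int = 0,
    direction: Direction = "from_to",
) -> PathDistanceResult:
    """Test whether two gene lists are closer in pathway space than chance.

    Computes the observed statistic, a permutation null of ``nperm`` random
    same-size list pairs, the left-tail add-one empirical p-value and the
    z-score ``(observed - mean(null)) / sd(null)``. The null hypothesis (the
    lists are no closer than random) is rejected for small p.
    """
    observed = nn_path_distance(D, from_list, to_list, direction)
    null = null_distribution(D, len(from_list), len(to_list), nperm, seed, direction)
    p = (1.0 + np.sum(null <= observed)) / (nperm + 1.0)
    sd = float(np.std(null, ddof=1)) if nperm > 1 else 0.0
    z = (observed - float(np.mean(null))) / sd if sd > 0 else float("nan")
    if sd == 0:
        logger.warning("degenerate null (zero spread): z-score undefined")
    return PathDistanceResult(
        observed=observed,
        null_sample=null,
        p_value=float(p),
        z_score=float(z),
        nperm=nperm,
        seed=seed,
        from_size=len(from_list),
        to_size=len(to_list),
        direction=direction,
    )


def write_distance_tsv(D: DistanceMatrix, path: str | Path) -> None:
    """Export as TSV with vertex names as header row and index column."""
    pd.DataFrame(D.d, index=list(D.labels), columns=list(D.labels)).to_csv(
        path, sep="\t", index_label="name"
    )


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    """Import a generic vertex-wise distance matrix (TSV, named rows/cols)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance TSV must have identical row and column names")
    return DistanceMatrix(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))
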