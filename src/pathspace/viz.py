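"""The three protocol plots, written to file.

* graph space: the layout scatter with optional marked genes;
* pathway space: the density landscape with optional marked genes;
* path distances: the permutation null as histogram + kernel-density curve,
  the observed statistic as a marker, and the shaded left-tail rejection
  region for a chosen alpha.

Plots are deterministic given their inputs (no jitter); styling is kept
minimal, with a dark "th3" landscape theme available for the density plot.
"""

from __future__ import annotations

from pathlib import Path
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import gaussian_kde

from .graphspace import GeneList, PathwayGraph, validate_membership
from .pathdist import PathDistanceResult
from .projection import DensityGrid

__all__ = [
    "PlotSpec",
    "rejection_threshold",
    "plot_graph_space",
    "plot_pathway_space",
    "plot_path_distances",
]


@dataclass(frozen=True)
class PlotSpec:
    """Cosmetic and annotation options shared by the three plot kinds."""

    marks: GeneList | None = None
    mark_color: str = "blue"
    mark_size: float = 2.0
    title: str = ""
    theme: str = "default"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def rejection_threshold(null_sample: np.ndarray, alpha: float = 0.05) -> float:
    """Left-tail empirical alpha-quantile of the null (type-7 interpolation).

    Observed values at or below this threshold fall in the rejection region
    drawn by :func:`plot_path_distances`.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("null_sample is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.quantile(null_sample, alpha, method="linear"))


def _check_marks(g: PathwayGraph, spec: PlotSpec) -> None:
    if spec.marks is not None:
        ok, missing = validate_membership(g, spec.marks)
        if not ok:
            raise KeyError(f"mark gene(s) not in graph: {missing}")


def _mark_points(ax, g: PathwayGraph, spec: PlotSpec) -> None:
    if spec.marks is None:
        return
    idx = g.index_of(spec.marks.ids)
    ax.scatter(g.layout[idx, 0], g.layout[idx, 1], s=30 * spec.mark_size,
               c=spec.mark_color, zorder=5, edgecolors="white", linewidths=0.5)
    for i in idx:
        ax.annotate(g.vertex_names[i], g.layout[i], textcoords="offset points",
                    xytext=(4, 4), fontsize=7, color=spec.mark_color)


def plot_graph_space(g: PathwayGraph, spec: PlotSpec, out_path: str | Path) -> Path:
    """Scatter of the layout with edges, highlighting any marked genes."""
    _check_marks(g, spec)
    fig, ax = plt.subplots(figsize=(6, 6))
    segs = np.array([[g.layout[i], g.layout[j]] for i, j in sorted(g.edges)])
    if len(segs):
        from matplotlib.collections import LineCollection

        ax.add_collection(LineCollection(segs, colors="0.8", linewidths=0.4, zorder=1))
    ax.scatter(g.layout[:, 0], g.layout[:, 1], s=4, c="0.4", zorder=2)
    _mark_points(ax, g, spec)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_aspect("equal")
    ax.set_title(spec.title or "Graph space")
    ax.set_xticks([])
    ax.set_yticks([])
    return _save(fig, out_path)


def plot_pathway_space(
    grid: DensityGrid, g: PathwayGraph, spec: PlotSpec, out_path: str | Path
) -> Path:
    """Density landscape heatmap over the unit square, with marked genes."""
    _check_marks(g, spec)
    dark = spec.theme == "th3"
    fig, ax = plt.subplots(figsize=(6.5, 6))
    cmap = plt.get_cmap("magma" if dark else "viridis").copy()
    cmap.set_bad("black" if dark else "white")
    im = ax.imshow(grid.values, origin="lower", extent=(0, 1, 0, 1),
                   cmap=cmap, vmin=0, vmax=1, interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8, label="density")
    _mark_points(ax, g, spec)
    if dark:
        fig.patch.set_facecolor("black")
        ax.set_title(spec.title or "Pathway space", color="white")
    else:
        ax.set_title(spec.title or "Pathway space")
    ax.set_xticks([])
    ax.set_yticks([])
    return _save(fig, out_path)


def plot_path_distances(
    result: PathDistanceResult, spec: PlotSpec, out_path: str | Path, z_axis: bool = False
) -> Path:
    """Null density with the observed statistic and the rejection region.

    Shows the permutation null as a histogram with a Silverman-bandwidth
    kernel-density curve, a triangle marker at the observed value, the shaded
    left tail up to ``rejection_threshold(null, alpha)``, and the p-value and
    z-score in the corner. With ``z_axis=True`` the x-axis is rescaled to
    z units (null mean 0, unit spread) so differently sized list pairs are
    comparable; the observed marker then sits at ``result.z_score``.
    """
    null = np.asarray(result.null_sample, dtype=float)
    observed = result.observed
    if z_axis:
        mu, sd = float(np.mean(null)), float(np.std(null, ddof=1))
        if sd <= 0:
            raise ValueError("cannot draw z-normalized axis: degenerate null")
        null = (null - mu) / sd
        observed = result.z_score
        xlabel = "path distance (z-score)"
    else:
        xlabel = "path distance (hops)"
    thr = rejection_threshold(null, spec.alpha)
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    ax.hist(null, bins=30, density=True, color="0.85", edgecolor="0.6")
    if np.std(null) > 0:
        kde = gaussian_kde(null, bw_method="silverman")
        xs = np.linspace(min(null.min(), observed), null.max(), 400)
        ax.plot(xs, kde(xs), color="0.2", lw=1.5)
        ax.fill_between(xs, kde(xs), where=xs <= thr, color="black", alpha=0.9,
                        label=f"rejection region (alpha={spec.alpha:g})")
    ax.axvline(thr, color="black", lw=0.8, ls="--")
    ax.plot([observed], [0], marker="^", color="red", markersize=12, clip_on=False,
            zorder=6, label="observed")
    z_txt = "undefined" if np.isnan(result.z_score) else f"{result.z_score:.2f}"
    ax.annotate(
        f"p = {result.p_value:.4g}\nz = {z_txt}",
        xy=(0.98, 0.95), xycoords="axes fraction", ha="right", va="top", fontsize=9,
        bbox=dict(boxstyle="round", fc="white", ec="0.7"),
    )
    ax.set_xlabel(xlabel)
    ax.set_ylabel("null density")
    ax.set_title(spec.title or
                 f"Path distance: {result.from_size} vs {result.to_size} genes, "
                 f"{result.nperm} permutations")
    ax.legend(loc="upper left", fontsize=8)
    return _save(fig, out_path)


def _save(fig, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
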