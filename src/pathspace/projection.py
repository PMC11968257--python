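"""Signal projection: turn per-vertex signal into a smoothed 2D density
landscape (circular projection) restricted to the graph's outline
(silhouette mapping).

Each vertex spreads its signal over a disk around its layout position using
a decay kernel; per-pixel contributions are aggregated and the grid is
rescaled to [0, 1]. The silhouette mask then hides pixels farther than a
silhouette radius from every vertex, so the landscape keeps the shape of the
vertex cloud rather than bleeding into empty space. Layouts are assumed
normalized to the unit square; radii are expressed as fractions of the unit
square diagonal, which makes them scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .graphspace import PathwayGraph

__all__ = ["ProjectionConfig", "DensityGrid", "circular_projection", "silhouette_mapping"]

_SQRT2 = float(np.sqrt(2.0))
# gaussian kernel support is truncated at u = 3 (3 sigma)
_GAUSS_TRUNC = 3.0


@dataclass(frozen=True)
class ProjectionConfig:
    """Tunable parameters of the projection and silhouette steps.

    grid_resolution
        Pixels per side of the square raster (>= 16).
    kernel
        ``linear``: K(u) = max(0, 1 - u); ``gaussian``: exp(-u^2/2) truncated
        at u = 3. u is Euclidean layout distance over ``projection_radius *
        sqrt(2)`` (radius as a fraction of the unit-square diagonal).
    projection_radius, silhouette_radius
        Fractions of the unit-square diagonal, in (0, 1].
    aggregation
        ``max``: pixel takes the strongest single-vertex contribution;
        ``sum-capped``: contributions add, then the grid is renormalized.
    """

    grid_resolution: int = 400
    kernel: Literal["linear", "gaussian"] = "linear"
    projection_radius: float = 0.05
    silhouette_radius: float = 0.03
    aggregation: Literal["max", "sum-capped"] = "max"

    def __post_init__(self) -> None:
        if self.grid_resolution < 16:
            raise ValueError("grid_resolution must be >= 16")
        for r in (self.projection_radius, self.silhouette_radius):
            if not 0 < r <= 1:
                raise ValueError("radii must be in (0, 1]")
        if self.kernel not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.aggregation not in ("max", "sum-capped"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dict(
            grid_resolution=self.grid_resolution,
            kernel=self.kernel,
            projection_radius=self.projection_radius,
            silhouette_radius=self.silhouette_radius,
            aggregation=self.aggregation,
        )))


@dataclass(frozen=True)
class DensityGrid:
    """Rasterized signal density over the unit square.

    ``values[i, j]`` is the density at the pixel with center
    ``((j + 0.5)/R, (i + 0.5)/R)`` — row-major, origin at the lower-left.
    ``mask[i, j]`` is True inside the silhouette; masked pixels carry NaN.
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square 2D array")
        object.__setattr__(self, "values", v)
        m = self.mask
        if m is None:
            m = np.ones_like(v, dtype=bool)
        m = np.asarray(m, dtype=bool)
        if m.shape != v.shape:
            raise ValueError("mask shape must match values")
        object.__setattr__(self, "mask", m)

    @property
    def resolution(self) -> int:
        return self.values.shape[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate vectors of pixel centers along each axis."""
        r = self.resolution
        c = (np.arange(r) + 0.5) / r
        return c, c

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.6g")


def _kernel_support(cfg: ProjectionConfig) -> float:
    """Radius (layout units) beyond which the kernel is exactly zero."""
    scale = cfg.projection_radius * _SQRT2
    return scale if cfg.kernel == "linear" else _GAUSS_TRUNC * scale


def _kernel_values(dist: np.ndarray, cfg: ProjectionConfig) -> np.ndarray:
    u = dist / (cfg.projection_radius * _SQRT2)
    if cfg.kernel == "linear":
        return np.maximum(0.0, 1.0 - u)
    k = np.exp(-0.5 * u * u)
    k[u > _GAUSS_TRUNC] = 0.0
    return k


def circular_projection(g: PathwayGraph, cfg: ProjectionConfig | None = None) -> DensityGrid:
    """Project per-vertex signal into a smoothed density raster.

    Each pixel aggregates ``signal[v] * K(dist(pixel, v))`` over vertices
    within the kernel support; the grid is then rescaled to [0, 1] by its
    maximum (an all-zero signal yields an all-zero grid, not an error).
    Only the pixel window around each vertex is touched, so cost is
    O(n_vertices * pixels-per-disk), not O(n_vertices * pixels).
    """
    cfg = cfg or ProjectionConfig()
    r = cfg.grid_resolution
    vals = np.zeros((r, r))
    support = _kernel_support(cfg)
    centers = (np.arange(r) + 0.5) / r
    for v in range(g.n_vertices):
        s = g.signal[v]
        if s == 0:
            continue
        x, y = g.layout[v]
        # pixel index window covering the kernel support disk
        j0 = max(0, int(np.floor((x - support) * r - 0.5)))
        j1 = min(r - 1, int(np.ceil((x + support) * r - 0.5)))
        i0 = max(0, int(np.floor((y - support) * r - 0.5)))
        i1 = min(r - 1, int(np.ceil((y + support) * r - 0.5)))
        if j1 < j0 or i1 < i0:
            continue
        dx = centers[j0:j1 + 1] - x
        dy = centers[i0:i1 + 1] - y
        dist = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2)
        contrib = s * _kernel_values(dist, cfg)
        if cfg.aggregation == "max":
            np.maximum(vals[i0:i1 + 1, j0:j1 + 1], contrib, out=vals[i0:i1 + 1, j0:j1 + 1])
        else:
            vals[i0:i1 + 1, j0:j1 + 1] += contrib
    peak = vals.max()
    if peak > 0:
        vals /= peak
    return DensityGrid(vals)


def silhouette_mapping(
    g: PathwayGraph, grid: DensityGrid, cfg: ProjectionConfig | None = None
) -> DensityGrid:
    """Mask the density raster to the neighborhood of the vertex cloud.

    A pixel is kept iff its center lies within ``silhouette_radius * sqrt(2)``
    (layout units) of the nearest vertex; everything else is set to NaN.
    Values inside the mask are unchanged.
    """
    cfg = cfg or ProjectionConfig()
    r = grid.resolution
    cx, cy = grid.pixel_centers()
    xx, yy = np.meshgrid(cx, cy)  # yy varies along rows (i), xx along cols (j)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    nearest, _ = cKDTree(g.layout).query(pts, k=1)
    mask = (nearest <= cfg.silhouette_radius * _SQRT2).reshape(r, r)
    vals = grid.values.copy()
    vals[~mask] = np.nan
    return DensityGrid(vals, mask)
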