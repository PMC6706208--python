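"""Area-based canopy cover and plot-level aggregation of light proxies.

Canopy cover is computed on a raster (default 4-m cells) as the fraction of
first returns classified as vegetation higher than 1 m above ground among
all first returns in the cell.  Plot values extract every cell whose center
falls inside the circular plot.  Point-based proxies (diffuse/direct light,
closure) are sampled on a regular camera grid (default 4x4, 4-m mesh,
16 images per plot) and summarized per plot as the mean of log-transformed
values and their standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata_io import NormalizedCloud

__all__ = [
    "CoverRaster",
    "PlotDefinition",
    "PlotLightSummary",
    "canopy_cover_raster",
    "plot_cover",
    "plot_camera_grid",
    "summarize_plot",
    "LOG_FLOOR",
]

LOG_FLOOR = 1e-3  # indices of exactly 0 are floored here before the log


@dataclass
class CoverRaster:
    """Canopy-cover ratios per cell; NaN where a cell has no first returns."""

    values: np.ndarray
    origin: tuple[float, float]  # lower-left corner
    cell_size: float = 4.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("cover raster must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates; row 0 is the northernmost row."""
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (ny - np.arange(ny) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class PlotDefinition:
    """Circular survey plot (default 200 m^2, radius ~7.98 m)."""

    id: str
    center: tuple[float, float]
    area: float = 200.0
    latitude: float = 47.0
    altitude: float = 500.0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("plot area must be positive")

    @property
    def radius(self) -> float:
        return math.sqrt(self.area / math.pi)


@dataclass
class PlotLightSummary:
    """Per-plot mean of log proxies and their spread.

    ``stats`` maps proxy name -> dict(mean_log, sd_log, n, n_floored).
    """

    plot_id: str
    stats: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"plot": self.plot_id, "proxy": k, **v} for k, v in self.stats.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canopy cover
# ---------------------------------------------------------------------------


def canopy_cover_raster(cloud: NormalizedCloud, cell_size: float = 4.0,
                        height_threshold: float = 1.0,
                        origin: tuple[float, float] | None = None) -> CoverRaster:
    """Rasterize canopy cover: per cell, vegetated first returns above the
    height threshold divided by all first returns."""
    first = cloud.is_first_return
    if not first.any():
        raise ValueError("cloud contains no first returns")
    x, y = cloud.x[first], cloud.y[first]
    tall_veg = (cloud.is_vegetation & (cloud.height_above_ground > height_threshold))[first]
    if origin is None:
        origin = (
            math.floor(x.min() / cell_size) * cell_size,
            math.floor(y.min() / cell_size) * cell_size,
        )
    col = np.floor((x - origin[0]) / cell_size).astype(int)
    row_from_bottom = np.floor((y - origin[1]) / cell_size).astype(int)
    if col.min() < 0 or row_from_bottom.min() < 0:
        raise ValueError("origin does not cover all first returns")
    nx, ny = col.max() + 1, row_from_bottom.max() + 1
    flat = row_from_bottom * nx + col
    total = np.bincount(flat, minlength=nx * ny).astype(float)
    veg = np.bincount(flat[tall_veg], minlength=nx * ny).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, veg / np.where(total > 0, total, 1), np.nan)
    values = ratio.reshape(ny, nx)[::-1, :]  # row 0 = north
    return CoverRaster(values, origin, cell_size)


def plot_cover(raster: CoverRaster, plot: PlotDefinition) -> tuple[float, float, int]:
    """Mean and sd of cover over cells whose center lies in the plot circle.

    Returns (mean, sd, n); sd is NaN for a single qualifying cell.
    """
    cx, cy = raster.cell_centers()
    inside = (cx - plot.center[0]) ** 2 + (cy - plot.center[1]) ** 2 <= plot.radius**2
    vals = raster.values[inside]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError(f"no raster cells with data inside plot {plot.id!r}")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return float(vals.mean()), sd, int(len(vals))


# ---------------------------------------------------------------------------
# camera grids and summaries
# ---------------------------------------------------------------------------


def plot_camera_grid(plot: PlotDefinition, mesh: float = 4.0,
                     n: int = 16) -> np.ndarray:
    """(n, 2) array of camera (x, y) on a sqrt(n) x sqrt(n) grid whose
    centroid coincides with the plot center (defaults: 16 points, 4-m mesh,
    offsets at +/-2 and +/-6 m)."""
    if mesh <= 0:
        raise ValueError("mesh must be positive")
    k = math.isqrt(n)
    if k * k != n:
        raise ValueError("n must be a perfect square")
    offs = (np.arange(k) - (k - 1) / 2.0) * mesh
    gx, gy = np.meshgrid(plot.center[0] + offs, plot.center[1] + offs)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _log_stats(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    floored = values < LOG_FLOOR
    logs = np.log(np.maximum(values, LOG_FLOOR))
    sd = float(np.std(logs, ddof=1)) if len(logs) > 1 else float("nan")
    return {
        "mean_log": float(logs.mean()),
        "sd_log": sd,
        "n": int(len(logs)),
        "n_floored": int(floored.sum()),
    }


def summarize_plot(plot_id: str, indices: pd.DataFrame,
                   cover_values: np.ndarray | None = None) -> PlotLightSummary:
    """Summarize the point-based indices sampled on the camera grid (columns
    ``diffuse_index``, ``direct_index``, ``canopy_closure``) and, optionally,
    the cover raster cells, as log-scale means and standard deviations."""
    summary = PlotLightSummary(plot_id)
    for proxy in ("diffuse_index", "direct_index", "canopy_closure"):
        if proxy in indices:
            summary.stats[proxy] = _log_stats(indices[proxy].to_numpy())
    if cover_values is not None:
        vals = np.asarray(cover_values, dtype=float)
        summary.stats["canopy_cover"] = _log_stats(vals[~np.isnan(vals)])
    return summary
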