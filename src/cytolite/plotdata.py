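"""Numeric substrates for the standard cytometry plots.

This module computes the data behind histograms, colored-density dot plots
and contour plots; rendering itself is left to the host plotting tooling
(matplotlib or anything else that takes edges/counts/grids).

The colored dot plot assigns each event the density of its 2D-histogram cell
(optionally box-smoothed), which is O(n) and fully deterministic — unlike a
kernel density estimate, there is no bandwidth to choose. Defaults of 256
bins per density axis and 128 histogram bins match typical cytometry display
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrityError, ParameterError
from .preprocess import AxisScale, LINEAR

__all__ = [
    "Histogram1D",
    "DensityGrid",
    "histogram_data",
    "density2d",
    "contour_levels",
]

DEFAULT_HIST_BINS = 128
DEFAULT_DENSITY_BINS = 256


@dataclass
class Histogram1D:
    """Equal-width histogram in transformed (gating/display) space."""

    edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray | None
    scale: AxisScale

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class DensityGrid:
    """2D histogram with an optional per-event density lookup column."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # shape (n_bins_x, n_bins_y)
    per_event_density: np.ndarray | None = None
    normalized: bool = False


def _smooth_counts(counts: np.ndarray) -> np.ndarray:
    """Window-3 moving average that conserves total mass.

    Each bin scatters a third of its mass to each neighbour; mass that would
    fall off an end of the axis stays in the end bin.
    """
    if len(counts) < 2:
        return counts.astype(np.float64)
    s = np.convolve(counts, np.full(3, 1.0 / 3.0), mode="same")
    s[0] += counts[0] / 3.0
    s[-1] += counts[-1] / 3.0
    return s


def histogram_data(
    values,
    scale: AxisScale = LINEAR,
    n_bins: int = DEFAULT_HIST_BINS,
    smooth: bool = False,
    value_range: tuple[float, float] | None = None,
) -> Histogram1D:
    """Histogram of ``values`` under ``scale``, with optional smoothing.

    Bins are equal-width in transformed space and right-open except the last
    (closed), so every in-range value lands in exactly one bin. Empty input
    yields zero counts over a default [0, 1] span rather than an error.
    ``value_range`` is given in transformed coordinates.
    """
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    t = scale.apply(np.asarray(values, dtype=np.float64).ravel())
    if value_range is None:
        if t.size == 0:
            value_range = (0.0, 1.0)
        else:
            lo, hi = float(t.min()), float(t.max())
            if lo == hi:  # degenerate span: widen symmetrically
                lo, hi = lo - 0.5, hi + 0.5
            value_range = (lo, hi)
    counts, edges = np.histogram(t, bins=n_bins, range=value_range)
    counts = counts.astype(np.float64)
    smoothed = _smooth_counts(counts) if smooth else None
    return Histogram1D(edges=edges, counts=counts, smoothed=smoothed, scale=scale)


def density2d(
    x,
    y,
    n_bins: tuple[int, int] = (DEFAULT_DENSITY_BINS, DEFAULT_DENSITY_BINS),
    scale_x: AxisScale = LINEAR,
    scale_y: AxisScale = LINEAR,
    normalized: bool = False,
    smooth: bool = False,
) -> DensityGrid:
    """2D histogram plus the per-event density used by the colored dot plot.

    ``per_event_density[e]`` is the (optionally 3×3 box-smoothed) density of
    the grid cell holding event ``e`` — the color value of that dot. With
    ``normalized`` the grid integrates to 1 over cell area.
    """
    tx = scale_x.apply(np.asarray(x, dtype=np.float64).ravel())
    ty = scale_y.apply(np.asarray(y, dtype=np.float64).ravel())
    if tx.shape != ty.shape:
        raise IntegrityError(
            f"x and y have different lengths ({tx.size} vs {ty.size})"
        )
    nx, ny = n_bins
    if nx < 1 or ny < 1:
        raise ParameterError("n_bins must be >= 1 on both axes")

    def span(v):
        if v.size == 0:
            return (0.0, 1.0)
        lo, hi = float(v.min()), float(v.max())
        return (lo - 0.5, hi + 0.5) if lo == hi else (lo, hi)

    grid, x_edges, y_edges = np.histogram2d(
        tx, ty, bins=[nx, ny], range=[span(tx), span(ty)]
    )
    if smooth:
        padded = np.pad(grid, 1, mode="edge")
        grid = sum(
            padded[1 + dx : 1 + dx + nx, 1 + dy : 1 + dy + ny]
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
        ) / 9.0
    if normalized:
        cell_area = np.outer(np.diff(x_edges), np.diff(y_edges))
        total = float((grid * cell_area).sum()) or 1.0
        grid = grid / total
        # with uniform cells this equals count / (n_total · cell_area)

    per_event = None
    if tx.size:
        ix = np.clip(np.searchsorted(x_edges, tx, side="right") - 1, 0, nx - 1)
        iy = np.clip(np.searchsorted(y_edges, ty, side="right") - 1, 0, ny - 1)
        per_event = grid[ix, iy]
    return DensityGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        density=grid,
        per_event_density=per_event,
        normalized=normalized,
    )


def contour_levels(grid: DensityGrid, n_levels: int) -> list[float]:
    """Equally spaced contour levels strictly inside (0, max density).

    Level *k* of *n* sits at ``k · max / (n + 1)``; an all-zero grid has no
    meaningful levels and yields an empty list.
    """
    if n_levels < 1:
        raise ParameterError("n_levels must be >= 1")
    peak = float(grid.density.max()) if grid.density.size else 0.0
    if peak <= 0:
        return []
    return [k * peak / (n_levels + 1) for k in range(1, n_levels + 1)]
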