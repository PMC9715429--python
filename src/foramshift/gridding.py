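"""Hovmöller (time × latitude) gridding of per-sample values.

Default resolution is 1 kyr × 2.5° latitude.  Time bins are left-closed
[t, t+dt) anchored at 0 ka; latitude bins are left-closed [l, l+dlat)
anchored at a configurable origin, so every sample lands in exactly one
cell.  Cells with no samples are missing (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ExtentError, ValidationError


@dataclass(frozen=True)
class GridField:
    """Aggregated values on a time-bin × latitude-bin grid."""

    time_edges: np.ndarray
    lat_edges: np.ndarray
    values: np.ndarray  # (n_time_bins, n_lat_bins), NaN where empty
    counts: np.ndarray  # per-cell sample counts

    @property
    def time_centers(self) -> np.ndarray:
        return (self.time_edges[:-1] + self.time_edges[1:]) / 2

    @property
    def lat_centers(self) -> np.ndarray:
        return (self.lat_edges[:-1] + self.lat_edges[1:]) / 2

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (time_bin, lat_bin, value, n) with bin left edges."""
        ti, li = np.meshgrid(np.arange(len(self.time_edges) - 1),
                             np.arange(len(self.lat_edges) - 1), indexing="ij")
        df = pd.DataFrame({
            "time_bin": self.time_edges[ti.ravel()],
            "lat_bin": self.lat_edges[li.ravel()],
            "value": self.values.ravel(),
            "n": self.counts.ravel().astype(int),
        })
        return df[df["n"] > 0].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def _edges(lo: float, hi: float, step: float, anchor: float) -> np.ndarray:
    """Left-closed bin edges of width ``step`` anchored at ``anchor``.

    The returned bins cover [lo, hi] inclusively: a value exactly on the
    last nominal edge gets its own [hi, hi+step) bin.
    """
    first = anchor + np.floor((lo - anchor) / step) * step
    last_bin = int(np.floor((hi - first) / step))
    return first + step * np.arange(last_bin + 2)


def grid_hovmoller(
    values,
    ages,
    latitudes,
    dt: float = 1.0,
    dlat: float = 2.5,
    aggregator: Callable[[np.ndarray], float] = np.mean,
    lat_origin: float = 0.0,
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> GridField:
    """Aggregate per-sample values onto the time × latitude grid.

    ``extent`` optionally fixes ((min_age, max_age), (min_lat, max_lat));
    samples falling outside a fixed extent raise :class:`ExtentError`.
    Without it the grid is sized to the data.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(ages, dtype=float)
    lat = np.asarray(latitudes, dtype=float)
    if not (len(v) == len(t) == len(lat)):
        raise ValidationError("values, ages and latitudes must have equal length")
    if len(v) == 0:
        raise ValidationError("nothing to grid")

    if extent is not None:
        (t_lo, t_hi), (l_lo, l_hi) = extent
        out = (t < t_lo) | (t >= t_hi) | (lat < l_lo) | (lat >= l_hi)
        if np.any(out):
            raise ExtentError(f"{int(out.sum())} sample(s) outside grid extent")
    else:
        (t_lo, t_hi), (l_lo, l_hi) = (t.min(), t.max()), (lat.min(), lat.max())

    time_edges = _edges(t_lo, t_hi, dt, 0.0)
    lat_edges = _edges(l_lo, l_hi, dlat, lat_origin)
    # right edge is exclusive: a sample exactly on the last edge opens a new bin
    ti = np.searchsorted(time_edges, t, side="right") - 1
    li = np.searchsorted(lat_edges, lat, side="right") - 1

    nt, nl = len(time_edges) - 1, len(lat_edges) - 1
    grid = np.full((nt, nl), np.nan)
    counts = np.zeros((nt, nl), dtype=int)
    order = np.lexsort((li, ti))
    cell = ti[order] * nl + li[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cell) != 0])
    bounds = np.r_[starts, len(cell)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        i, j = divmod(cell[a], nl)
        members = v[order[a:b]]
        grid[i, j] = aggregator(members)
        counts[i, j] = b - a
    return GridField(time_edges=time_edges, lat_edges=lat_edges, values=grid, counts=counts)
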