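"""Configurational landscapes: 2D KDE maps, density maxima, state labels.

Population densities over descriptor pairs (e.g. d-Omega or phase-position)
are estimated with a Gaussian product kernel whose per-axis bandwidth is
Scott's rule, h_i = sigma_i * n^(-1/6), times a ``bandwidth_adjust``
multiplier (default 1.0, the plotting-library default behaviour).  Angular
axes are treated as linear on (-180, 180]; populations straddling the seam
split across it — a documented limitation, matching maps drawn on linear
axes.

For small samples the kernel sum is evaluated exactly; above a size
threshold the samples are histogrammed onto the output grid and convolved
with the Gaussian kernel, which agrees with the exact sum to within the
grid resolution and keeps 1e5-sample maps fast.  Densities are not
renormalised after evaluation, so the integral-equals-one invariant is a
genuine check that the grid covers the support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter

_EXACT_MAX_N = 2000


@dataclass
class DensityMap:
    """Gridded 2D probability density over two named descriptor axes."""

    x_name: str
    y_name: str
    x: np.ndarray  # (nx,) grid coordinates
    y: np.ndarray  # (ny,)
    density: np.ndarray  # (nx, ny), >= 0
    bandwidth: tuple[float, float]
    n_samples: int
    note: str = "Gaussian product-kernel KDE; density integrates to ~1 over the grid"

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.y, axis=1), self.x))


@dataclass(frozen=True)
class StateRegion:
    """Axis-aligned rectangle in a descriptor plane.

    Boundary convention: closed lower edge, open upper edge
    (lo <= value < hi), so adjacent regions tile the plane without overlap.
    Lower ``priority`` values win where regions overlap.
    """

    name: str
    x_axis: str
    y_axis: str
    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]
    priority: int = 0


@dataclass
class StateRegions:
    regions: list[StateRegion] = field(default_factory=list)

    def __iter__(self):
        return iter(self.regions)


#: Default active-arrangement box for the TrkA receptor: both rotation
#: angles between 100 and 150 degrees (the most populated density maximum
#: in the phase-position plane).
TRKA_ACTIVE_REGION = StateRegion(
    name="active",
    x_axis="phase",
    y_axis="position",
    x_bounds=(100.0, 150.0),
    y_bounds=(100.0, 150.0),
    priority=0,
)


def scott_bandwidth(values: np.ndarray, n_axes: int = 2) -> float:
    """Scott's rule bandwidth for one axis of an n_axes-dimensional KDE."""
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) * len(values) ** (-1.0 / (n_axes + 4)))


def kde_density_2d(
    x,
    y,
    bandwidth_adjust: float = 1.0,
    gridsize: int = 200,
    pad_bandwidths: float = 3.0,
    x_name: str = "x",
    y_name: str = "y",
) -> DensityMap:
    """Gaussian-kernel density of paired samples on a regular grid.

    Non-finite pairs (e.g. frames flagged undefined) are dropped.  At least
    10 finite pairs and non-zero variance on both axes are required.  The
    grid spans the data range padded by ``pad_bandwidths`` bandwidths.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 finite points, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance on an axis: KDE bandwidth undefined")
    hx = scott_bandwidth(x) * bandwidth_adjust
    hy = scott_bandwidth(y) * bandwidth_adjust
    gx = np.linspace(x.min() - pad_bandwidths * hx, x.max() + pad_bandwidths * hx, gridsize)
    gy = np.linspace(y.min() - pad_bandwidths * hy, y.max() + pad_bandwidths * hy, gridsize)
    if n <= _EXACT_MAX_N:
        dens = _kde_exact(x, y, gx, gy, hx, hy)
    else:
        dens = _kde_binned(x, y, gx, gy, hx, hy)
    return DensityMap(
        x_name=x_name, y_name=y_name, x=gx, y=gy, density=dens,
        bandwidth=(hx, hy), n_samples=n,
    )


def _kde_exact(x, y, gx, gy, hx, hy):
    ux = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)  # (nx, n)
    uy = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2)  # (ny, n)
    dens = ux @ uy.T  # sum over samples of the product kernel
    return dens / (len(x) * 2 * np.pi * hx * hy)


def _kde_binned(x, y, gx, gy, hx, hy):
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]
    edges_x = np.concatenate([gx - dx / 2, [gx[-1] + dx / 2]])
    edges_y = np.concatenate([gy - dy / 2, [gy[-1] + dy / 2]])
    hist, _, _ = np.histogram2d(x, y, bins=[edges_x, edges_y])
    smooth = gaussian_filter(hist, sigma=(hx / dx, hy / dy), mode="constant", truncate=8.0)
    return smooth / (len(x) * dx * dy)


def find_maxima(
    dmap: DensityMap,
    min_separation: tuple[float, float] = (0.0, 0.0),
    min_height_fraction: float = 0.05,
) -> pd.DataFrame:
    """Local density maxima, ranked by height (rank 1 = global mode).

    A grid point is a candidate if it is the maximum of its 3x3
    neighbourhood and at least ``min_height_fraction`` of the global
    maximum.  Candidates within ``min_separation`` (per-axis, data units)
    of an already-accepted higher peak are merged into it.  Returns a table
    with columns ``rank, x, y, density``; may be empty for a flat map.
    """
    d = dmap.density
    local = (d == maximum_filter(d, size=3, mode="nearest")) & (d > 0)
    if d.max() > 0:
        local &= d >= min_height_fraction * d.max()
    ii, jj = np.nonzero(local)
    order = np.argsort(d[ii, jj])[::-1]
    peaks = []
    sx, sy = min_separation
    for k in order:
        px, py, ph = dmap.x[ii[k]], dmap.y[jj[k]], d[ii[k], jj[k]]
        if any(abs(px - q[0]) <= sx and abs(py - q[1]) <= sy for q in peaks):
            continue
        peaks.append((px, py, ph))
    return pd.DataFrame(
        [(r + 1, px, py, ph) for r, (px, py, ph) in enumerate(peaks)],
        columns=["rank", "x", "y", "density"],
    )


def classify_arrangement(
    descriptors: pd.DataFrame, regions: StateRegions | list[StateRegion]
) -> tuple[pd.Series, dict[str, float]]:
    """Label each frame by the highest-priority region containing it.

    Frames outside every region (or with NaN on a region axis) are labelled
    ``"other"``.  Returns the per-frame labels and the population fractions
    per label; fractions sum to 1.
    """
    region_list = sorted(regions, key=lambda r: r.priority)
    for r in region_list:
        for ax in (r.x_axis, r.y_axis):
            if ax not in descriptors.columns:
                raise ValueError(f"region {r.name!r} needs axis {ax!r} absent from table")
    labels = pd.Series("other", index=descriptors.index, dtype=object)
    unassigned = np.ones(len(descriptors), dtype=bool)
    for r in region_list:
        x = descriptors[r.x_axis].to_numpy(dtype=float)
        y = descriptors[r.y_axis].to_numpy(dtype=float)
        inside = (
            (x >= r.x_bounds[0]) & (x < r.x_bounds[1])
            & (y >= r.y_bounds[0]) & (y < r.y_bounds[1])
            & unassigned
        )
        labels[inside] = r.name
        unassigned &= ~inside
    counts = labels.value_counts()
    fractions = {name: float(c) / len(labels) for name, c in counts.items()}
    return labels, fractions


def cterm_distance_modes(
    descriptors: pd.DataFrame,
    labels: pd.Series,
    column: str = "dC",
    bandwidth_adjust: float = 1.0,
    gridsize: int = 512,
    min_frames: int = 10,
) -> pd.DataFrame:
    """Per-state 1D KDE mode of a termini-distance column.

    States with fewer than ``min_frames`` finite frames are skipped with a
    warning.  Returns columns ``state, mode, n_frames``.
    """
    rows = []
    for state in pd.unique(labels):
        vals = descriptors.loc[labels == state, column].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_frames:
            warnings.warn(
                f"state {state!r} has only {len(vals)} frames; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        if vals.std() == 0:
            mode = float(vals[0])  # degenerate: all frames identical
        else:
            h = vals.std(ddof=1) * len(vals) ** (-0.2) * bandwidth_adjust
            grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, gridsize)
            dens = np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / h) ** 2).sum(axis=1)
            mode = float(grid[np.argmax(dens)])
        rows.append((state, mode, len(vals)))
    return pd.DataFrame(rows, columns=["state", "mode", "n_frames"])
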