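"""Kernel-density estimation with mode-based subpopulation detection.

Used in 1D on hub clustering coefficients ("is the hub set one
population?") and in 2D on degree x bottleneck-score coordinates of the
hub-bottleneck controllers ("do the controllers split into
subpopulations, and which sit alone in low-density regions?").

The estimator is a Gaussian product kernel with an independent bandwidth
per dimension (Silverman's rule by default), evaluated on a regular grid
spanning the data range plus three bandwidths.  Subpopulations are the
grid-local maxima of the density; each point is attributed to the mode
reached by discrete gradient ascent from its nearest grid cell.  Points
whose local density falls below a small fraction of the peak density
(``density_quantile``, default 0.05) are reported as isolated instead.
Because degree and bottleneck score live on incommensurate scales, 2D
input is z-standardized internally; reported mode locations are mapped
back to the original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np


@dataclass
class Subpopulation:
    mode: np.ndarray          # mode location, original coordinates
    members: list[int]        # indices into the input point array
    peak_density: float


@dataclass
class KDEResult:
    dims: int
    grid: tuple[np.ndarray, ...]      # per-axis coordinates (original scale)
    density: np.ndarray               # shape (len(axis0), ...) on the working scale
    bandwidth: np.ndarray             # per-dimension, working scale
    points: np.ndarray                # (n, dims), original coordinates
    standardized: bool
    scale_offset: np.ndarray          # working = (original - offset) / scale
    scale_factor: np.ndarray
    subpopulations: Optional[list[Subpopulation]] = None
    isolated: Optional[list[int]] = None

    def integral(self) -> float:
        """Numerical integral of the density over the grid (working scale)."""
        d = self.density
        for ax in range(self.dims):
            coords = (self.grid[ax] - self.scale_offset[ax]) / self.scale_factor[ax]
            d = np.trapezoid(d, coords, axis=0)
        return float(d)


def silverman_bandwidth(points: np.ndarray) -> np.ndarray:
    """Per-dimension rule-of-thumb bandwidth h_i = sd_i * (4/((d+2)n))^(1/(d+4)).

    Dimensions with zero spread get a floor of 1e-6 times the data range
    (or 1e-6 absolute when the range itself is zero), keeping degenerate
    inputs finite.
    """
    n, d = points.shape
    sd = points.std(axis=0)
    if n > 1:
        factor = (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
        h = sd * factor
    else:
        h = np.ones(d)
    rng = points.max(axis=0) - points.min(axis=0)
    floor = np.where(rng > 0, 1e-6 * rng, 1e-6)
    return np.maximum(h, floor)


def _gauss(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)


def kde_estimate(
    points,
    bandwidth=None,
    grid_size: int = 128,
    pad_bandwidths: float = 3.0,
    standardize: Optional[bool] = None,
) -> KDEResult:
    """Evaluate a Gaussian-kernel density on a regular grid.

    Parameters
    ----------
    points
        (n,) or (n, 1) or (n, 2) array of coordinates; all finite.
    bandwidth
        Scalar or per-dimension smoothing parameter (working scale);
        Silverman's rule when None.
    grid_size
        Grid points per axis (>= 128 resolves the mode structure the
        subpopulation step relies on).
    pad_bandwidths
        Grid margin beyond the data range, in bandwidth units; 3 keeps the
        truncated kernel mass (hence the integral error) below 1%.
    standardize
        z-standardize coordinates before smoothing; defaults to True in 2D
        (incommensurate axes) and False in 1D.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.size == 0:
        raise ValueError("kde_estimate requires at least one point")
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    n, d = pts.shape
    if d not in (1, 2):
        raise ValueError("only 1D and 2D estimation is supported")
    if standardize is None:
        standardize = d == 2

    offset = np.zeros(d)
    scale = np.ones(d)
    if standardize:
        offset = pts.mean(axis=0)
        sd = pts.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
    work = (pts - offset) / scale

    if bandwidth is None:
        h = silverman_bandwidth(work)
    else:
        h = np.broadcast_to(np.atleast_1d(np.asarray(bandwidth, dtype=float)), (d,)).copy()
        if np.any(h <= 0):
            raise ValueError("bandwidth must be positive")

    axes_work = []
    for i in range(d):
        lo = work[:, i].min() - pad_bandwidths * h[i]
        hi = work[:, i].max() + pad_bandwidths * h[i]
        axes_work.append(np.linspace(lo, hi, grid_size))

    # product kernel: per-axis Gaussian matrices combined by tensor product
    kmats = [
        _gauss((axes_work[i][:, None] - work[None, :, i]) / h[i]) / h[i]
        for i in range(d)
    ]
    if d == 1:
        density = kmats[0].mean(axis=1)
    else:
        density = kmats[0] @ kmats[1].T / n  # (grid, grid)

    grid_original = tuple(axes_work[i] * scale[i] + offset[i] for i in range(d))
    return KDEResult(
        dims=d,
        grid=grid_original,
        density=density,
        bandwidth=h,
        points=pts,
        standardized=standardize,
        scale_offset=offset,
        scale_factor=scale,
    )


def _neighbors(idx: tuple[int, ...], shape: tuple[int, ...]):
    deltas = [t for t in product((-1, 0, 1), repeat=len(shape)) if any(t)]
    for dt in deltas:
        nb = tuple(i + s for i, s in zip(idx, dt))
        if all(0 <= i < m for i, m in zip(nb, shape)):
            yield nb


def _ascend(start: tuple[int, ...], density: np.ndarray) -> tuple[int, ...]:
    """Discrete gradient ascent to the attracting local maximum."""
    cur = start
    while True:
        best = cur
        best_val = density[cur]
        for nb in _neighbors(cur, density.shape):
            if density[nb] > best_val:
                best, best_val = nb, density[nb]
        if best == cur:
            return cur
        cur = best


def point_densities(kde: KDEResult) -> np.ndarray:
    """Exact kernel density at each input point (working scale)."""
    work = (kde.points - kde.scale_offset) / kde.scale_factor
    n, d = work.shape
    total = np.ones((n, n))
    for i in range(d):
        total *= _gauss((work[:, None, i] - work[None, :, i]) / kde.bandwidth[i]) / kde.bandwidth[i]
    return total.mean(axis=1)


def _persistence_basins(density: np.ndarray, merge_ratio: float):
    """Watershed-by-descending-flood basin labels with persistence merging.

    Cells are processed in order of decreasing density; a cell with no
    processed neighbor founds a new basin (a mode), otherwise it joins its
    highest-peak processed neighbor.  When a cell touches two basins it is
    their saddle: basins whose saddle density exceeds ``merge_ratio`` times
    the lower peak are low-prominence wiggles of one population and are
    merged.  Returns (basin label per cell, root -> peak density).
    """
    shape = density.shape
    flat = density.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    basin = np.full(flat.size, -1, dtype=int)
    parent: dict[int, int] = {}
    peak: dict[int, float] = {}

    def find(r: int) -> int:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    for flat_idx in order:
        idx = np.unravel_index(flat_idx, shape)
        roots = []
        for nb in _neighbors(idx, shape):
            nb_flat = np.ravel_multi_index(nb, shape)
            if basin[nb_flat] >= 0:
                r = find(basin[nb_flat])
                if r not in roots:
                    roots.append(r)
        if not roots:
            basin[flat_idx] = flat_idx
            parent[flat_idx] = flat_idx
            peak[flat_idx] = float(flat[flat_idx])
            continue
        roots.sort(key=lambda r: -peak[r])
        main = roots[0]
        basin[flat_idx] = main
        for other in roots[1:]:
            saddle = float(flat[flat_idx])
            if saddle >= merge_ratio * min(peak[main], peak[other]):
                parent[other] = main
    labels = np.array([find(r) for r in basin]).reshape(shape)
    peaks = {r: peak[r] for r in set(labels.ravel())}
    return labels, peaks


def find_subpopulations(
    kde: KDEResult, density_quantile: float = 0.05, merge_ratio: float = 0.5
) -> KDEResult:
    """Attribute every input point to a density mode or mark it isolated.

    The isolation level is ``density_quantile`` times the peak grid density;
    points whose local density falls strictly below it are isolated, the
    rest are assigned by discrete gradient ascent on the grid.  Modes whose
    separating saddle rises above ``merge_ratio`` of the lower peak are
    merged (low-prominence wiggles of a single population), so sampling
    noise does not fragment one cluster into several.
    """
    if not 0 <= density_quantile < 1:
        raise ValueError("density_quantile must be in [0, 1)")
    if not 0 < merge_ratio <= 1:
        raise ValueError("merge_ratio must be in (0, 1]")
    level = density_quantile * float(kde.density.max())
    work = (kde.points - kde.scale_offset) / kde.scale_factor
    axes_work = [
        (kde.grid[i] - kde.scale_offset[i]) / kde.scale_factor[i]
        for i in range(kde.dims)
    ]

    pdens = point_densities(kde)
    isolated = [int(i) for i in np.nonzero(pdens < level)[0]]
    isolated_set = set(isolated)

    labels, _ = _persistence_basins(kde.density, merge_ratio)
    groups: dict[tuple[int, ...], list[int]] = {}
    for i in range(len(work)):
        if i in isolated_set:
            continue
        start = tuple(
            int(np.argmin(np.abs(axes_work[ax] - work[i, ax])))
            for ax in range(kde.dims)
        )
        mode_cell = _ascend(start, kde.density)
        root = tuple(np.unravel_index(labels[mode_cell], kde.density.shape))
        groups.setdefault(root, []).append(i)

    subpops = [
        Subpopulation(
            mode=np.array([kde.grid[ax][m[ax]] for ax in range(kde.dims)]),
            members=sorted(members),
            peak_density=float(kde.density[m]),
        )
        for m, members in sorted(groups.items())
    ]
    subpops.sort(key=lambda s: -s.peak_density)
    kde.subpopulations = subpops
    kde.isolated = isolated
    return kde


def kde_analysis(
    points, bandwidth=None, density_quantile: float = 0.05, **kwargs
) -> KDEResult:
    """Convenience: estimate the density, then detect subpopulations."""
    return find_subpopulations(
        kde_estimate(points, bandwidth=bandwidth, **kwargs),
        density_quantile=density_quantile,
    )
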