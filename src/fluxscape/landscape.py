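"""Potential landscapes from stochastic steady-state ensembles.

The landscape is the negative log of the steady-state probability
distribution, U = -ln(Pss), estimated on a 2D projection by
histogramming post-transient Langevin samples of the two chosen
coordinates (a true marginal over the remaining dimensions).  Basins
are found by watershed descent on the smoothed potential; the saddle
between two basins is the minimax value over connecting grid paths,
computed exactly by an ascending union-find flood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "LandscapeGrid",
    "SaddlePoint",
    "BarrierReport",
    "estimate_pss",
    "potential_from_pss",
    "locate_basins_saddles",
    "compute_barriers",
    "landscape_from_samples",
]


@dataclass
class LandscapeGrid:
    axis_x: str
    axis_y: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    pss: np.ndarray  # (nx, ny) probability mass per bin, sums to 1 on unmasked
    u: np.ndarray | None = None
    mask: np.ndarray | None = None  # True where no samples
    smoothing: float = 1.0

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def bin_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0]))

    def density(self) -> np.ndarray:
        """Probability density (mass / bin area)."""
        return self.pss / self.bin_area

    def locate(self, x: float, y: float) -> tuple:
        i = int(np.clip(np.searchsorted(self.x_edges, x) - 1, 0, len(self.x_edges) - 2))
        j = int(np.clip(np.searchsorted(self.y_edges, y) - 1, 0, len(self.y_edges) - 2))
        return i, j


@dataclass
class SaddlePoint:
    index: tuple  # grid cell (i, j)
    u: float
    basins: tuple  # pair of basin labels it separates
    name: str = ""
    position: tuple = ()


@dataclass
class BarrierReport:
    barriers: dict  # (saddle_name, basin_label) -> barrier height
    saddles: list = field(default_factory=list)
    minima: dict = field(default_factory=dict)  # basin label -> (i, j, u)

    def get(self, saddle: str, basin: str) -> float:
        return self.barriers[(saddle, basin)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"saddle": s, "basin": b, "barrier": v} for (s, b), v in self.barriers.items()
        ]
        return pd.DataFrame(rows)


def estimate_pss(samples, axes, bins=100, ranges=None, names=None,
                 smoothing=1.0) -> LandscapeGrid:
    """2D histogram of the projected coordinates, normalized to 1.

    ``samples`` is either an (n, d) array of full states together with
    ``names`` and ``axes`` node ids, or an (n, 2) array of projected
    pairs.  ``ranges`` defaults to the observed sample range expanded by
    5% on each side.  Marginalization over all other coordinates is
    implicit in histogramming only the two axes.
    """
    samples = np.asarray(samples, float)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise ValueError("need a nonempty (n_samples, dim) array")
    if samples.shape[1] == 2 and names is None:
        xy = samples
        ax_x, ax_y = (axes if axes is not None else ("x", "y"))
    else:
        if names is None:
            raise ValueError("full-dimensional samples require node names")
        ix, iy = names.index(axes[0]), names.index(axes[1])
        xy = samples[:, (ix, iy)]
        ax_x, ax_y = axes
    if ranges is None:
        lo = xy.min(axis=0)
        hi = xy.max(axis=0)
        pad = 0.05 * np.maximum(hi - lo, 1e-9)
        ranges = ((lo[0] - pad[0], hi[0] + pad[0]), (lo[1] - pad[1], hi[1] + pad[1]))
    counts, x_edges, y_edges = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=bins, range=ranges
    )
    pss = counts / counts.sum()
    grid = LandscapeGrid(
        axis_x=ax_x, axis_y=ax_y, x_edges=x_edges, y_edges=y_edges,
        pss=pss, mask=counts == 0, smoothing=smoothing,
    )
    grid.n_samples = int(counts.sum())
    return grid


def potential_from_pss(grid: LandscapeGrid) -> LandscapeGrid:
    """Fill ``u = -ln(pss)``; empty bins are masked and capped at max(u) + 1.

    The cap keeps minimax path searches finite while preserving the
    ordering of visited bins; U is defined up to an additive constant.
    """
    pss = grid.pss
    mask = grid.mask if grid.mask is not None else pss <= 0
    u = np.full_like(pss, np.nan)
    with np.errstate(divide="ignore"):
        u[~mask] = -np.log(pss[~mask])
    cap = np.nanmax(u) + 1.0 if np.any(~mask) else 1.0
    u[mask] = cap
    grid.u = u
    grid.mask = mask
    return grid


def _smoothed_u(grid: LandscapeGrid) -> np.ndarray:
    """Potential recomputed from smoothed pss (extremum detection only)."""
    if grid.smoothing <= 0:
        return grid.u
    p = gaussian_filter(grid.pss, grid.smoothing)
    u = np.full_like(p, np.nan)
    pos = p > 0
    u[pos] = -np.log(p[pos])
    cap = np.nanmax(u[pos]) + 1.0
    u[~pos] = cap
    return u


def locate_basins_saddles(grid: LandscapeGrid, min_prominence=0.5,
                          min_basin_mass=None):
    """Find local minima, basin labels, and inter-basin minimax saddles.

    Cells are flooded in ascending order of the (smoothed) potential
    with 4-connectivity union-find; the first contact between two
    basins is their minimax saddle, which agrees with exhaustive
    path-enumeration on small grids.  Masked (empty) cells participate
    at the cap value so disconnected sample islands still join.  A
    basin is merged into its neighbour when its prominence (saddle
    height above the minimum) is below ``min_prominence`` or when the
    probability mass at its minimum is below ``min_basin_mass``
    (default: the mass of 3 samples, suppressing histogram-noise
    minima).

    Returns ``(minima, saddles, basin_map)`` where minima is a list of
    ``(i, j, u)``, saddles a list of :class:`SaddlePoint` and basin_map
    an integer label array (-1 on masked cells).
    """
    if grid.u is None:
        raise ValueError("call potential_from_pss first")
    u = _smoothed_u(grid)
    nx, ny = u.shape
    mask = grid.mask if grid.mask is not None else np.zeros_like(u, bool)
    if min_basin_mass is None:
        n_samples = getattr(grid, "n_samples", None)
        min_basin_mass = (3.0 / n_samples) if n_samples else 0.0
    order = np.argsort(u, axis=None)
    parent = {}
    root_min = {}  # root -> (i, j, u) of its minimum
    label_map = -np.ones((nx, ny), int)
    saddles_raw = []

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    visited = np.zeros((nx, ny), bool)
    for flat in order:
        i, j = divmod(int(flat), ny)
        neighbors = []
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and visited[a, b]:
                neighbors.append((a, b))
        visited[i, j] = True
        cell = (i, j)
        if not neighbors:
            parent[cell] = cell
            root_min[cell] = (i, j, float(u[i, j]))
            continue
        roots = {find(n) for n in neighbors}
        roots = sorted(roots, key=lambda r: root_min[r][2])
        main = roots[0]
        parent[cell] = main
        for other in roots[1:]:
            # first contact between two catchments: minimax saddle at u[i, j]
            saddles_raw.append((float(u[i, j]), (i, j), main, other))
            parent[other] = main

    # merge shallow basins: process saddles in ascending order
    kept_roots = set(root_min)
    effective = {r: r for r in root_min}

    def eff(r):
        while effective[r] != r:
            effective[r] = effective[effective[r]]
            r = effective[r]
        return r

    saddle_records = []
    smooth_pss = gaussian_filter(grid.pss, grid.smoothing) if grid.smoothing > 0 else grid.pss
    for su, cell, r1, r2 in sorted(saddles_raw, key=lambda t: t[0]):
        a, b = eff(r1), eff(r2)
        if a == b:
            continue
        ua, ub = root_min[a][2], root_min[b][2]
        shallower, deeper = (a, b) if ua > ub else (b, a)
        i_s, j_s, _ = root_min[shallower]
        noise_floor = smooth_pss[i_s, j_s] < min_basin_mass
        if su - root_min[shallower][2] < min_prominence or noise_floor:
            effective[shallower] = deeper
            kept_roots.discard(shallower)
        else:
            saddle_records.append((su, cell, a, b))

    minima = sorted((root_min[r] for r in kept_roots), key=lambda t: t[2])
    root_label = {r: k for k, r in enumerate(
        sorted(kept_roots, key=lambda r: root_min[r][2]))}

    for i in range(nx):
        for j in range(ny):
            if mask[i, j]:
                continue
            r = eff(find((i, j)))
            if r in root_label:
                label_map[i, j] = root_label[r]
    # a lone surviving root on masked ground can happen on pathological
    # grids; guard against empty results
    if not kept_roots:
        flat = int(np.argmin(np.where(mask, np.inf, u)))
        i, j = divmod(flat, ny)
        minima = [(i, j, float(u[i, j]))]
        label_map[~mask] = 0
        return minima, [], label_map

    saddles = []
    for su, cell, r1, r2 in saddle_records:
        a, b = eff(r1), eff(r2)
        if a == b or a not in root_label or b not in root_label:
            continue
        pair = tuple(sorted((root_label[a], root_label[b])))
        if any(s.basins == pair for s in saddles):
            continue  # keep only the lowest contact per pair
        saddles.append(
            SaddlePoint(
                index=cell, u=float(grid.u[cell]), basins=pair,
                position=(float(grid.x_centers[cell[0]]), float(grid.y_centers[cell[1]])),
            )
        )
    return minima, saddles, label_map


def compute_barriers(grid: LandscapeGrid, minima, saddles,
                     basin_labels=None) -> BarrierReport:
    """Barrier height U(saddle) - U(basin minimum) for each adjacent pair.

    ``basin_labels`` optionally maps basin index -> name (e.g. N/I/P/G);
    saddle names are assigned s1, s2, ... in ascending saddle height
    unless already named.  Barriers are invariant to an additive
    constant in U.
    """
    names = {}
    if basin_labels:
        names.update(basin_labels)
    barriers = {}
    minima_by_basin = {}
    for k, (i, j, uval) in enumerate(minima):
        # re-evaluate on the raw (unsmoothed) grid for consistency with saddles
        minima_by_basin[k] = (i, j, float(grid.u[i, j]))
    out_saddles = []
    for idx, s in enumerate(sorted(saddles, key=lambda s: s.u)):
        name = s.name or f"s{idx + 1}"
        s.name = name
        out_saddles.append(s)
        for basin in s.basins:
            if basin not in minima_by_basin:
                continue
            bname = names.get(basin, str(basin))
            barrier = s.u - minima_by_basin[basin][2]
            barriers[(name, bname)] = max(float(barrier), 0.0)
    labeled_minima = {
        names.get(k, str(k)): v for k, v in minima_by_basin.items()
    }
    return BarrierReport(barriers=barriers, saddles=out_saddles, minima=labeled_minima)


def landscape_from_samples(samples, axes, names=None, bins=100, ranges=None,
                           smoothing=1.0, min_prominence=0.5):
    """Convenience: histogram -> potential -> basins/saddles -> barriers."""
    grid = estimate_pss(samples, axes, bins=bins, ranges=ranges, names=names,
                        smoothing=smoothing)
    potential_from_pss(grid)
    minima, saddles, labels = locate_basins_saddles(grid, min_prominence=min_prominence)
    report = compute_barriers(grid, minima, saddles)
    return grid, minima, saddles, labels, report
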