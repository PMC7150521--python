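"""Steady-state probability flux, entropy production, and oscillation metrics.

On the 2D projection the steady-state flux is reconstructed from the
projected Fokker-Planck current,

    J = mu * rho - D * grad(rho),

where ``rho`` is the stationary density on the grid, ``mu`` the
conditional mean drift of the two projected coordinates (estimated per
bin from the sample ensemble), and ``D`` the diffusion coefficient of
the simulation that produced the samples.  The entropy production rate
follows as EPR = sum |J|^2 / (D rho) over the grid; it vanishes exactly
in detailed balance and is nonnegative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import LandscapeGrid, estimate_pss, potential_from_pss
from .simulate import SimulationConfig, as_dynamics, langevin_ensemble

__all__ = [
    "FluxField",
    "NonequilibriumSummary",
    "OscillationMetrics",
    "flux_field",
    "nonequilibrium_summary",
    "oscillation_metrics",
    "scan_nonequilibrium",
    "rotation_coherence",
    "switching_times",
]


@dataclass
class FluxField:
    grid: LandscapeGrid
    jx: np.ndarray
    jy: np.ndarray
    drift_x: np.ndarray
    drift_y: np.ndarray
    noise: float
    low_confidence: np.ndarray  # bins with < min_count samples
    divergence_rms: float = float("nan")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.jx, self.jy)


@dataclass
class NonequilibriumSummary:
    mean_flux: float
    epr: float
    mean_flux_se: float = float("nan")
    epr_se: float = float("nan")
    parameter_value: float | None = None

    def as_dict(self) -> dict:
        return {
            "mean_flux": self.mean_flux, "epr": self.epr,
            "mean_flux_se": self.mean_flux_se, "epr_se": self.epr_se,
            "parameter_value": self.parameter_value,
        }


@dataclass
class OscillationMetrics:
    flux_integral: float
    coherence: float
    period: float
    t_g_to_p: float
    t_p_to_g: float


def _conditional_drift(grid: LandscapeGrid, states, drifts, names, min_count=10):
    """Per-bin mean drift of the projected coordinates."""
    ix = names.index(grid.axis_x)
    iy = names.index(grid.axis_y)
    x = states[:, ix]
    y = states[:, iy]
    nx, ny = grid.pss.shape
    bi = np.clip(np.searchsorted(grid.x_edges, x) - 1, 0, nx - 1)
    bj = np.clip(np.searchsorted(grid.y_edges, y) - 1, 0, ny - 1)
    flat = bi * ny + bj
    counts = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)
    sx = np.bincount(flat, weights=drifts[:, ix], minlength=nx * ny).reshape(nx, ny)
    sy = np.bincount(flat, weights=drifts[:, iy], minlength=nx * ny).reshape(nx, ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(counts > 0, sx / np.maximum(counts, 1), 0.0)
        my = np.where(counts > 0, sy / np.maximum(counts, 1), 0.0)
    return mx, my, counts < min_count


def flux_field(grid: LandscapeGrid, samples, system=None, drifts=None, names=None,
               noise: float = 0.01, min_count: int = 10) -> FluxField:
    """Reconstruct the projected steady-state probability flux.

    ``samples`` are full-dimensional post-transient states; their
    instantaneous drifts are either supplied or evaluated through the
    model.  The density gradient is taken by central differences, and a
    discrete divergence check is reported (zero in a perfect steady
    state).
    """
    samples = np.asarray(samples, float)
    if system is not None:
        dyn = as_dynamics(system)
        names = list(dyn.names)
        drifts = dyn.f(samples)
    if drifts is None or names is None:
        raise ValueError("provide either system or (drifts, names)")
    mx, my, lowconf = _conditional_drift(grid, samples, np.asarray(drifts, float),
                                         names, min_count)
    rho = grid.density()
    dx = grid.x_edges[1] - grid.x_edges[0]
    dy = grid.y_edges[1] - grid.y_edges[0]
    drho_dx, drho_dy = np.gradient(rho, dx, dy)
    jx = mx * rho - noise * drho_dx
    jy = my * rho - noise * drho_dy
    djx, _ = np.gradient(jx, dx, dy)
    _, djy = np.gradient(jy, dx, dy)
    div = djx + djy
    ok = ~grid.mask if grid.mask is not None else np.ones_like(jx, bool)
    divergence_rms = float(np.sqrt(np.mean(div[ok] ** 2))) if ok.any() else float("nan")
    return FluxField(
        grid=grid, jx=jx, jy=jy, drift_x=mx, drift_y=my, noise=noise,
        low_confidence=lowconf, divergence_rms=divergence_rms,
    )


def nonequilibrium_summary(flux: FluxField, n_boot: int = 0, rng=None,
                           samples=None, system=None,
                           parameter_value=None) -> NonequilibriumSummary:
    """Mean flux magnitude and entropy production rate of a flux field.

    EPR = sum over unmasked bins of |J|^2 / (D * rho) * bin_area; with
    ``n_boot`` > 0 and the original samples provided, bootstrap
    standard errors over sample resampling are attached.
    """
    grid = flux.grid

    def _summary(fl):
        ok = ~grid.mask if grid.mask is not None else np.ones_like(fl.jx, bool)
        mag = fl.magnitude()[ok]
        mean_flux = float(mag.mean()) if mag.size else 0.0
        rho = grid.density()[ok]
        pos = rho > 0
        epr = float(np.sum(fl.magnitude()[ok][pos] ** 2 / (fl.noise * rho[pos]))
                    * grid.bin_area)
        return mean_flux, epr

    mean_flux, epr = _summary(flux)
    mf_se = epr_se = float("nan")
    if n_boot and samples is not None and system is not None:
        rng = np.random.default_rng(rng)
        samples = np.asarray(samples, float)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(samples), len(samples))
            sub = samples[idx]
            g = estimate_pss(sub, (grid.axis_x, grid.axis_y),
                             bins=grid.pss.shape[0],
                             ranges=((grid.x_edges[0], grid.x_edges[-1]),
                                     (grid.y_edges[0], grid.y_edges[-1])),
                             names=list(as_dynamics(system).names))
            potential_from_pss(g)
            fl = flux_field(g, sub, system=system, noise=flux.noise)
            vals.append(_summary(fl))
        vals = np.asarray(vals)
        mf_se, epr_se = vals.std(axis=0, ddof=1)
    return NonequilibriumSummary(
        mean_flux=mean_flux, epr=epr, mean_flux_se=float(mf_se),
        epr_se=float(epr_se), parameter_value=parameter_value,
    )


def rotation_coherence(xy: np.ndarray, window: int = 50) -> float:
    """Directedness of rotation about the trajectory centroid, in [0, 1].

    The trajectory is cut into windows; each window votes by the sign
    of its net angular displacement.  The majority fraction is rescaled
    so that pure diffusion gives ~0 and deterministic rotation gives 1.
    """
    xy = np.asarray(xy, float)
    c = xy.mean(axis=0)
    ang = np.unwrap(np.arctan2(xy[:, 1] - c[1], xy[:, 0] - c[0]))
    n_win = max(len(ang) // window, 1)
    votes = []
    for k in range(n_win):
        seg = ang[k * window:(k + 1) * window + 1]
        if len(seg) >= 2:
            votes.append(np.sign(seg[-1] - seg[0]))
    votes = np.asarray(votes)
    if votes.size == 0:
        return 0.0
    f_major = max((votes > 0).mean(), (votes < 0).mean())
    return float(np.clip(2.0 * (f_major - 0.5), 0.0, 1.0))


def switching_times(times, xy, regions: dict) -> dict:
    """Mean first-passage durations between region entries along a path.

    ``regions`` maps labels to (center, radius) in projection space.
    Returns mean durations label_a->label_b for consecutive distinct
    region entries.
    """
    times = np.asarray(times, float)
    xy = np.asarray(xy, float)
    labels_seq = []
    for label, (center, radius) in regions.items():
        inside = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1]) < radius
        labels_seq.append((label, inside))
    current = None
    t_enter = None
    events = []  # (label, entry time)
    for k in range(len(times)):
        here = None
        for label, inside in labels_seq:
            if inside[k]:
                here = label
                break
        if here is not None and here != current:
            events.append((here, times[k]))
            current = here
    durations = {}
    for (la, ta), (lb, tb) in zip(events[:-1], events[1:]):
        durations.setdefault((la, lb), []).append(tb - ta)
    return {k: float(np.mean(v)) for k, v in durations.items()}


def oscillation_metrics(cycle, flux: FluxField, times, states, names,
                        regions: dict, window: int = 50) -> OscillationMetrics:
    """Flux loop integral, rotation coherence, and G<->P switching times.

    ``cycle`` is a deterministic limit-cycle attractor (kind="cycle");
    the flux integral sums |J| * ds along the discretized cycle on the
    grid; switching times are measured on the stochastic trajectory.
    """
    if cycle is None or getattr(cycle, "kind", "") != "cycle":
        raise ValueError("oscillation metrics require a detected limit cycle")
    grid = flux.grid
    ix = names.index(grid.axis_x)
    iy = names.index(grid.axis_y)
    loop = np.asarray(cycle.location, float)[:, (ix, iy)]
    mag = flux.magnitude()
    integral = 0.0
    for a, b in zip(loop[:-1], loop[1:]):
        mid = 0.5 * (a + b)
        i, j = grid.locate(*mid)
        integral += mag[i, j] * float(np.hypot(*(b - a)))
    xy = np.asarray(states, float)[:, (ix, iy)]
    coher = rotation_coherence(xy, window=window)
    durs = switching_times(times, xy, regions)
    t_gp = durs.get(("G", "P"), float("nan"))
    t_pg = durs.get(("P", "G"), float("nan"))
    return OscillationMetrics(
        flux_integral=float(integral), coherence=coher,
        period=float(cycle.period or np.nan), t_g_to_p=t_gp, t_p_to_g=t_pg,
    )


def scan_nonequilibrium(model, path: str, grid_values, config: SimulationConfig,
                        axes=("LDH", "PDH"), bins=60, n_walkers=200,
                        ranges=None) -> pd.DataFrame:
    """Mean flux and EPR along a parameter scan (fixed seed per point).

    Each grid point runs the full pipeline: Langevin ensemble ->
    projected landscape -> flux field -> summary.  Seeds are derived
    from ``config.seed`` plus the grid index so the sampling noise is
    independent but reproducible.
    """
    from .network import set_parameter

    rows = []
    for k, v in enumerate(np.asarray(grid_values, float)):
        m = set_parameter(model, path, v)
        cfg = config.with_(seed=(config.seed * 7919 + k) % (2**31 - 1))
        samples = langevin_ensemble(m, cfg, n_walkers=n_walkers)
        dyn = as_dynamics(m)
        g = estimate_pss(samples, axes, bins=bins, names=list(dyn.names), ranges=ranges)
        potential_from_pss(g)
        fl = flux_field(g, samples, system=m, noise=float(np.max(cfg.noise)))
        s = nonequilibrium_summary(fl, parameter_value=float(v))
        rows.append({"parameter": path, "value": float(v),
                     "mean_flux": s.mean_flux, "epr": s.epr})
    return pd.DataFrame(rows)
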