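"""Barrier-based sensitivity analysis and therapeutic-target screening.

Sensitivity: each interaction parameter is scaled by a small relative
delta (default +1%), the landscape is re-estimated with the same random
seed as the baseline (common random numbers, so Monte-Carlo noise
largely cancels in the difference), and the change of every named
barrier is reported.

Therapy: the drift of a gene or enzyme node is deformed by a constant,
F'(x_i) = F(x_i) + c_i (c > 0 activation, c < 0 inhibition), and the
stability of the cancer basins is re-measured; a negative barrier
change destabilizes the corresponding cancer state, which counts as a
positive therapeutic effect.  Oscillation therapy scores interventions
by the change of the center-island barrier of the ring-shaped
(limit-cycle) landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import estimate_pss, potential_from_pss, locate_basins_saddles
from .network import NetworkDynamics, NetworkModel, get_parameter, set_parameter
from .simulate import SimulationConfig, as_dynamics, langevin_ensemble

__all__ = [
    "SensitivityReport",
    "TherapyReport",
    "sensitivity_scan",
    "classify_regulations",
    "therapy_scan",
    "oscillation_therapy",
    "barrier_table",
    "basin_stability",
]

_ARCHETYPES = {"N": (0.0, 0.0), "G": (1.0, 0.0), "P": (0.0, 1.0), "I": (0.55, 0.55)}


def _label_minima(minima, grid):
    """Map basin index -> N/I/P/G by nearest archetype in normalized coords."""
    coords = np.array(
        [[grid.x_centers[i], grid.y_centers[j]] for i, j, _u in minima], float
    )
    if len(coords) == 0:
        return {}
    span = np.maximum(coords.max(axis=0), 1e-9)
    Z = coords / span
    out = {}
    taken = set()
    # greedy assignment, closest pairs first
    cand = []
    for k, z in enumerate(Z):
        for lab, ref in _ARCHETYPES.items():
            cand.append((np.hypot(z[0] - ref[0], z[1] - ref[1]), k, lab))
    for _d, k, lab in sorted(cand):
        if k in out or lab in taken:
            continue
        out[k] = lab
        taken.add(lab)
    return out


def barrier_table(samples, axes, names, bins=70, ranges=None, smoothing=1.0,
                  min_prominence=0.4) -> dict:
    """Landscape barriers keyed by (basin-pair, basin) with N/I/P/G labels.

    Returns ``{"barriers": {(pair, basin): h}, "minima": {label: u},
    "n_basins": k}`` where ``pair`` is a sorted label tuple.
    """
    grid = estimate_pss(samples, axes, bins=bins, ranges=ranges, names=names,
                        smoothing=smoothing)
    potential_from_pss(grid)
    minima, saddles, _labels = locate_basins_saddles(grid, min_prominence=min_prominence)
    labels = _label_minima(minima, grid)
    barriers = {}
    for s in saddles:
        a, b = s.basins
        if a not in labels or b not in labels:
            continue
        pair = tuple(sorted((labels[a], labels[b])))
        for idx in (a, b):
            i, j, _ = minima[idx]
            barrier = max(float(s.u - grid.u[i, j]), 0.0)
            key = (pair, labels[idx])
            barriers[key] = min(barriers.get(key, np.inf), barrier)
    return {
        "barriers": barriers,
        "minima": {labels[k]: float(grid.u[i, j]) for k, (i, j, _u) in enumerate(minima)
                   if k in labels},
        "n_basins": len(minima),
    }


def basin_stability(table: dict, label: str) -> float:
    """Stability proxy of a basin: its lowest escape barrier."""
    vals = [v for (pair, basin), v in table["barriers"].items() if basin == label]
    return float(min(vals)) if vals else float("nan")


@dataclass
class SensitivityReport:
    delta: float
    baseline: dict
    deltas: dict  # parameter path -> {(pair, basin): dBarrier}
    qualitative: dict = field(default_factory=dict)  # path -> message
    standard_errors: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for path, d in self.deltas.items():
            for (pair, basin), v in d.items():
                rows.append({
                    "parameter": path, "saddle": "|".join(pair), "basin": basin,
                    "delta_barrier": v,
                    "se": self.standard_errors.get(path, {}).get((pair, basin), np.nan),
                })
        return pd.DataFrame(rows)


@dataclass
class TherapyReport:
    c: float
    baseline: dict
    effects: dict  # intervention name -> {"P": dBarrier, "G": dBarrier}
    qualitative: dict = field(default_factory=dict)

    def ranking(self, cancer_type: str) -> list:
        """Interventions sorted by therapeutic effect on basin 'P' or 'G'.

        More negative barrier change = stronger destabilization of the
        cancer state = better ranking.
        """
        items = [(name, eff[cancer_type]) for name, eff in self.effects.items()
                 if np.isfinite(eff.get(cancer_type, np.nan))]
        return sorted(items, key=lambda t: t[1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, eff in self.effects.items():
            rows.append({"intervention": name,
                         "d_barrier_P": eff.get("P", np.nan),
                         "d_barrier_G": eff.get("G", np.nan)})
        return pd.DataFrame(rows)


def _pipeline_samples(system, config: SimulationConfig, n_walkers: int):
    return langevin_ensemble(system, config, n_walkers=n_walkers)


def _delta_barriers(base: dict, pert: dict):
    """Paired differences on the common barrier keys; None if topology changed."""
    if set(base["barriers"]) != set(pert["barriers"]) or base["n_basins"] != pert["n_basins"]:
        return None
    return {k: pert["barriers"][k] - base["barriers"][k] for k in base["barriers"]}


def sensitivity_scan(model: NetworkModel, parameters=None, delta: float = 0.01,
                     config: SimulationConfig | None = None, axes=("LDH", "PDH"),
                     bins=70, n_walkers=220, n_blocks: int = 0) -> SensitivityReport:
    """Relative perturbation of interaction parameters, change per barrier.

    ``parameters`` defaults to every regulation fold-change
    (``gamma:src->tgt``).  Each perturbed landscape reuses the baseline
    seed; a perturbation that changes the basin count is reported in
    ``qualitative`` rather than as numbers.  With ``n_blocks > 0`` the
    walker ensemble is split into blocks and paired per-block
    differences give standard errors.
    """
    if config is None:
        raise ValueError("a SimulationConfig is required")
    if parameters is None:
        parameters = [f"gamma:{e.source}->{e.target}" for e in model.edges]
    dyn = as_dynamics(model)
    names = list(dyn.names)
    base_samples = _pipeline_samples(model, config, n_walkers)
    ix, iy = names.index(axes[0]), names.index(axes[1])
    lo = base_samples[:, (ix, iy)].min(axis=0)
    hi = base_samples[:, (ix, iy)].max(axis=0)
    pad = 0.15 * (hi - lo)
    ranges = ((lo[0] - pad[0], hi[0] + pad[0]), (lo[1] - pad[1], hi[1] + pad[1]))
    base = barrier_table(base_samples, axes, names, bins=bins, ranges=ranges)

    def _blocks(samples):
        if not n_blocks:
            return []
        per = len(samples) // n_blocks
        return [barrier_table(samples[k * per:(k + 1) * per], axes, names,
                              bins=bins, ranges=ranges) for k in range(n_blocks)]

    base_blocks = _blocks(base_samples)
    deltas, qualitative, ses = {}, {}, {}
    for path in parameters:
        value = get_parameter(model, path)
        pert_model = set_parameter(model, path, value * (1.0 + delta))
        pert_samples = _pipeline_samples(pert_model, config, n_walkers)
        pert = barrier_table(pert_samples, axes, names, bins=bins, ranges=ranges)
        d = _delta_barriers(base, pert)
        if d is None:
            qualitative[path] = (
                f"basin topology changed ({base['n_basins']} -> {pert['n_basins']} basins)"
            )
            continue
        deltas[path] = d
        if n_blocks:
            pert_blocks = _blocks(pert_samples)
            per_block = []
            for bb, pb in zip(base_blocks, pert_blocks):
                db = _delta_barriers(bb, pb)
                if db is not None:
                    per_block.append(db)
            if len(per_block) >= 2:
                ses[path] = {
                    k: float(np.std([db[k] for db in per_block if k in db], ddof=1)
                             / np.sqrt(len(per_block)))
                    for k in d
                }
    return SensitivityReport(delta=delta, baseline=base, deltas=deltas,
                             qualitative=qualitative, standard_errors=ses)


def classify_regulations(report: SensitivityReport) -> pd.DataFrame:
    """Classify parameters as promoting the OXPHOS or glycolysis cancer state.

    A regulation promotes the OXPHOS state when it raises the OXPHOS
    basin's escape barrier more than the intermediate basin's (the
    OXPHOS state gains stability relative to the intermediate state);
    analogously for glycolysis.  Ties give 'neither'.  Where standard
    errors are available, classifications are suppressed unless the
    relevant difference exceeds twice its standard error.
    """
    rows = []
    for path, d in report.deltas.items():
        def stab(label):
            vals = [v for (pair, basin), v in d.items() if basin == label]
            return min(vals) if vals else np.nan

        dp, dg, di = stab("P"), stab("G"), stab("I")
        label = "neither"
        if np.isfinite(dp) and np.isfinite(di) and dp > di and (
                not np.isfinite(dg) or dp >= dg):
            label = "promotes-OXPHOS"
        elif np.isfinite(dg) and np.isfinite(di) and dg > di:
            label = "promotes-glycolysis"
        se_map = report.standard_errors.get(path, {})
        if se_map:
            ref = max(abs(v) for v in d.values())
            max_se = max(se_map.values())
            if ref < 2.0 * max_se:
                label = "neither"
        rows.append({"parameter": path, "d_P": dp, "d_G": dg, "d_I": di,
                     "classification": label})
    return pd.DataFrame(rows)


def _intervention_name(node: str, c: float) -> str:
    return ("+" if c > 0 else "-") + node


def therapy_scan(model: NetworkModel, interventions, c: float = 2e-4,
                 config: SimulationConfig | None = None, axes=("LDH", "PDH"),
                 bins=70, n_walkers=220) -> TherapyReport:
    """Constant-force deformation screening of gene/enzyme targets.

    ``interventions`` is a list of node ids, (node, sign) pairs, or
    tuples of nodes applied jointly (combination therapy).  Metabolite
    targets are rejected.  Effects are paired-seed changes of the P and
    G basin escape barriers; negative = destabilizing = therapeutic.
    """
    if config is None:
        raise ValueError("a SimulationConfig is required")
    dyn = as_dynamics(model)
    names = list(dyn.names)
    base_samples = _pipeline_samples(model, config, n_walkers)
    ix, iy = names.index(axes[0]), names.index(axes[1])
    lo = base_samples[:, (ix, iy)].min(axis=0)
    hi = base_samples[:, (ix, iy)].max(axis=0)
    pad = 0.15 * (hi - lo)
    ranges = ((lo[0] - pad[0], hi[0] + pad[0]), (lo[1] - pad[1], hi[1] + pad[1]))
    base = barrier_table(base_samples, axes, names, bins=bins, ranges=ranges)
    effects, qualitative = {}, {}
    for iv in interventions:
        if isinstance(iv, str):
            targets = [(iv, c)]
        elif isinstance(iv, tuple) and len(iv) == 2 and isinstance(iv[1], (int, float)) \
                and not isinstance(iv[1], bool) and isinstance(iv[0], str):
            targets = [(iv[0], float(iv[1]))]
        else:
            targets = [(n, c) if isinstance(n, str) else (n[0], float(n[1])) for n in iv]
        biases = {}
        for node, ci in targets:
            role = model.get_node(node).role
            if role == "metabolite":
                raise ValueError(f"therapy targets genes/enzymes, {node!r} is a metabolite")
            biases[node] = biases.get(node, 0.0) + ci
        name = "&".join(_intervention_name(n, ci) for n, ci in targets)
        pert_dyn = NetworkDynamics(model, biases=biases)
        pert_samples = _pipeline_samples(pert_dyn, config, n_walkers)
        pert = barrier_table(pert_samples, axes, names, bins=bins, ranges=ranges)
        d = _delta_barriers(base, pert)
        if d is None:
            qualitative[name] = (
                f"basin topology changed ({base['n_basins']} -> {pert['n_basins']} basins)"
            )
            effects[name] = {"P": np.nan, "G": np.nan}
            continue
        def stab_change(label):
            vals = [v for (pair, basin), v in d.items() if basin == label]
            return float(min(vals)) if vals else np.nan
        effects[name] = {"P": stab_change("P"), "G": stab_change("G")}
    return TherapyReport(c=c, baseline=base, effects=effects, qualitative=qualitative)


def _points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd ray casting; poly is (k, 2) closed or open."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), bool)
    px, py = poly[:, 0], poly[:, 1]
    n = len(poly)
    j = n - 1
    for i in range(n):
        cond = ((py[i] > y) != (py[j] > y)) & (
            x < (px[j] - px[i]) * (y - py[i]) / (py[j] - py[i] + 1e-300) + px[i]
        )
        inside ^= cond
        j = i
    return inside


def center_island_barrier(grid, cycle_xy: np.ndarray) -> float:
    """Barrier of the oscillation: max U inside the ring minus min U on it.

    ``cycle_xy`` is the projected deterministic limit cycle.  The
    "island" is the region enclosed by the cycle polygon; the ring
    level is the minimum potential along the cycle cells.
    """
    centers = np.array(
        [(x, y) for x in grid.x_centers for y in grid.y_centers]
    )
    inside = _points_in_polygon(centers, cycle_xy).reshape(
        len(grid.x_centers), len(grid.y_centers)
    )
    ring_u = []
    for x, y in cycle_xy:
        i, j = grid.locate(x, y)
        ring_u.append(grid.u[i, j])
    ok = ~grid.mask if grid.mask is not None else np.ones_like(grid.u, bool)
    island = inside & ok
    if not island.any() or not ring_u:
        return float("nan")
    return float(np.max(grid.u[island]) - np.min(ring_u))


def oscillation_therapy(model: NetworkModel, interventions, c: float = 2e-4,
                        config: SimulationConfig | None = None, axes=("LDH", "PDH"),
                        bins=70, n_walkers=220, cycle_detector=None) -> TherapyReport:
    """Score interventions by the change of the center-island barrier.

    Requires a baseline limit cycle (Mexican-hat landscape); an
    intervention that removes the cycle is reported qualitatively.
    ``cycle_detector(system)`` must return the deterministic cycle
    attractor; the default uses :func:`~fluxscape.simulate.detect_limit_cycle`.
    """
    from .simulate import detect_limit_cycle

    if config is None:
        raise ValueError("a SimulationConfig is required")
    dyn = as_dynamics(model)
    names = list(dyn.names)
    ix, iy = names.index(axes[0]), names.index(axes[1])

    def detect(system):
        if cycle_detector is not None:
            return cycle_detector(system)
        det_cfg = config.with_(horizon=max(config.horizon, 400.0), noise=0.0)
        return detect_limit_cycle(system, det_cfg, axes=axes)

    base_cycle = detect(model)
    if base_cycle is None:
        raise ValueError("no baseline limit cycle: oscillation therapy needs one")

    def island(system, cycle):
        samples = _pipeline_samples(system, config, n_walkers)
        grid = estimate_pss(samples, axes, bins=bins, names=names)
        potential_from_pss(grid)
        return center_island_barrier(grid, np.asarray(cycle.location)[:, (ix, iy)])

    base_barrier = island(model, base_cycle)
    effects, qualitative = {}, {}
    for iv in interventions:
        node, ci = (iv, c) if isinstance(iv, str) else (iv[0], float(iv[1]))
        if model.get_node(node).role == "metabolite":
            raise ValueError(f"therapy targets genes/enzymes, {node!r} is a metabolite")
        name = _intervention_name(node, ci)
        pert_dyn = NetworkDynamics(model, biases={node: ci})
        cyc = detect(pert_dyn)
        if cyc is None:
            qualitative[name] = "limit cycle lost (monostabilized)"
            effects[name] = {"island": np.nan}
            continue
        effects[name] = {"island": island(pert_dyn, cyc) - base_barrier}
    rep = TherapyReport(c=c, baseline={"island": base_barrier}, effects=effects,
                        qualitative=qualitative)
    return rep
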