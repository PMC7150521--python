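"""Dominant transition paths by minimization of a discretized action.

The most probable escape route between attractors of ``dx = F(x) dt +
sqrt(2 D) dW`` minimizes the Freidlin-Wentzell action

    S[x] = int ||x' - F(x)||^2 / (4 D) dt.

Discretized on waypoints, the per-segment time step is eliminated
analytically (the optimum moves each segment at the local drift speed),
leaving the geometric form

    S = sum ( ||dx_k|| ||F_k|| - dx_k . F_k ) / (2 D),

which is minimized over interior waypoint positions with L-BFGS using
an analytic gradient (model Jacobians taken by batched finite
differences).  Downhill segments of a gradient flow cost zero, so the
action localizes on the uphill (instanton) part; forward and backward
paths of non-gradient systems generally differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .simulate import Attractor, as_dynamics

__all__ = ["TransitionPath", "minimize_action", "path_table", "geometric_action"]


@dataclass
class TransitionPath:
    source: str
    target: str
    waypoints: np.ndarray  # (k, n) including endpoints
    action: float
    converged: bool
    n_iter: int = 0

    def projected(self, names, axes) -> np.ndarray:
        ix, iy = names.index(axes[0]), names.index(axes[1])
        return self.waypoints[:, (ix, iy)]

    def to_frame(self, names) -> pd.DataFrame:
        df = pd.DataFrame(self.waypoints, columns=names)
        df.insert(0, "waypoint", np.arange(len(df)))
        return df


def geometric_action(path: np.ndarray, f, noise: float) -> float:
    """Time-optimized (geometric) Freidlin-Wentzell action of a waypoint path."""
    path = np.asarray(path, float)
    d = np.diff(path, axis=0)
    mid = 0.5 * (path[:-1] + path[1:])
    F = f(mid)
    nd = np.linalg.norm(d, axis=1)
    nF = np.linalg.norm(F, axis=1)
    return float(np.sum(nd * nF - np.sum(d * F, axis=1)) / (2.0 * noise))


def _action_and_grad(z, x0, x1, f, noise, dim, eps=1e-6, kappa=2.0):
    """Action and gradient w.r.t. interior waypoints (batched FD Jacobians).

    A parameterization penalty ``kappa * N * Var(segment length) /
    mean(segment length)^2`` keeps waypoints near equal arclength; it
    vanishes for the uniformly spaced optimum and prevents the
    discretization from tunnelling long segments through zeros of the
    drift.
    """
    interior = z.reshape(-1, dim)
    path = np.vstack([x0, interior, x1])
    d = np.diff(path, axis=0)
    mid = 0.5 * (path[:-1] + path[1:])
    F = f(mid)
    nd = np.linalg.norm(d, axis=1)
    nF = np.linalg.norm(F, axis=1)
    S = float(np.sum(nd * nF - np.sum(d * F, axis=1)) / (2 * noise))

    # dS/dd_k and dS/dF_k
    with np.errstate(invalid="ignore", divide="ignore"):
        dS_dd = (np.where(nd > 0, nF / np.maximum(nd, 1e-300), 0.0)[:, None] * d - F) / (2 * noise)
        dS_dF = (np.where(nF > 0, nd / np.maximum(nF, 1e-300), 0.0)[:, None] * F - d) / (2 * noise)

    # Jacobian-vector products J(mid_k)^T dS_dF_k via batched finite differences
    n_seg = len(mid)
    pert = np.repeat(mid, dim, axis=0)
    pert[np.arange(n_seg * dim), np.tile(np.arange(dim), n_seg)] += eps
    Fp = f(pert).reshape(n_seg, dim, dim)  # Fp[k, i, :] = F(mid_k + eps e_i)
    JT_v = np.einsum("kid,kd->ki", (Fp - F[:, None, :]) / eps, dS_dF)

    grad = np.zeros_like(path)
    # d terms: d_k = x_{k+1} - x_k
    grad[1:] += dS_dd
    grad[:-1] -= dS_dd
    # F terms: mid_k = (x_k + x_{k+1}) / 2
    grad[1:] += 0.5 * JT_v
    grad[:-1] += 0.5 * JT_v

    # equal-arclength penalty (pure parameterization term)
    mean_nd = nd.mean()
    if mean_nd > 0 and kappa > 0:
        dev = nd - mean_nd
        pen = kappa * np.sum(dev**2) / mean_nd**2
        S_total = S + pen
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = d / np.maximum(nd, 1e-300)[:, None]
        n_seg = len(nd)
        # d pen / d nd_k, including the mean_nd dependence
        dpen_dnd = (2 * kappa / mean_nd**2) * dev \
            - (2 * kappa * np.sum(dev**2) / mean_nd**3) / n_seg \
            - (2 * kappa / (mean_nd**2 * n_seg)) * np.sum(dev) * 0.0
        gpen = dpen_dnd[:, None] * unit
        grad[1:] += gpen
        grad[:-1] -= gpen
    else:
        S_total = S
    return S_total, grad[1:-1].ravel()


def minimize_action(system, source, target, noise: float, n_waypoints: int = 24,
                    seed: int = 0, n_restarts: int = 4, jitter: float = 0.05,
                    maxiter: int = 400, nonnegative: bool | None = None) -> TransitionPath:
    """Minimize the discretized action between two point attractors.

    Initialized from the straight segment (plus seeded jitter on the
    restarts); returns the best of ``n_restarts``.  The action is
    nonnegative and zero only if the path is a flow line of the
    deterministic drift.
    """
    if n_waypoints < 16:
        raise ValueError("n_waypoints must be >= 16")
    dyn = as_dynamics(system)
    if nonnegative is None:
        nonnegative = bool(getattr(dyn, "nonnegative", False))
    f = dyn.f

    def loc(a):
        return np.asarray(a.location if isinstance(a, Attractor) else a, float)

    x0, x1 = loc(source), loc(target)
    lab0 = getattr(source, "label", "") or "src"
    lab1 = getattr(target, "label", "") or "tgt"
    if np.allclose(x0, x1):
        return TransitionPath(source=lab0, target=lab1,
                              waypoints=np.vstack([x0, x1]), action=0.0,
                              converged=True)
    dim = dyn.dimension
    t = np.linspace(0, 1, n_waypoints)[1:-1, None]
    straight = x0 + t * (x1 - x0)
    rng = np.random.default_rng(seed)
    scale = np.linalg.norm(x1 - x0) / np.sqrt(dim)
    best = None
    for r in range(max(1, n_restarts)):
        init = straight.copy()
        if r > 0:
            init = init + rng.normal(0, jitter * scale, init.shape)
            if nonnegative:
                init = np.maximum(init, 0.0)
        res = minimize(
            _action_and_grad, init.ravel(), args=(x0, x1, f, noise, dim),
            jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * init.size if nonnegative else None,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    waypoints = np.vstack([x0, best.x.reshape(-1, dim), x1])
    action = geometric_action(waypoints, f, noise)  # penalty-free value
    return TransitionPath(
        source=lab0, target=lab1, waypoints=waypoints,
        action=max(float(action), 0.0), converged=bool(best.success),
        n_iter=int(best.nit),
    )


def path_table(system, attractors, noise: float, pairs=None, n_waypoints: int = 24,
               seed: int = 0, **kw) -> list:
    """Dominant paths for the requested ordered pairs of attractor labels.

    With ``pairs=None`` all ordered pairs are computed; for the
    reference quadristable model pass the eight pairs N<->I, I<->P,
    N<->P, I<->G.  Deterministic given the seed.
    """
    by_label = {a.label: a for a in attractors}
    if pairs is None:
        labels = list(by_label)
        pairs = [(a, b) for a in labels for b in labels if a != b]
    out = []
    for k, (a, b) in enumerate(pairs):
        out.append(
            minimize_action(system, by_label[a], by_label[b], noise,
                            n_waypoints=n_waypoints, seed=seed + 101 * k, **kw)
        )
    return out
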