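"""Synthetic inputs: analytically tractable toy systems, four-state
expression matrices, and reference-configuration scaffolding.

The toy registry is the oracle backbone of the test suite: every toy
declares machine-checkable truths (fixed points, barriers, stationary
densities, closed-form flux/EPR, periods) against which the landscape,
flux, and path machinery is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import shifted_hill

__all__ = [
    "ToyModel",
    "SyntheticExpressionSpec",
    "make_toy",
    "toy_names",
    "make_synthetic_expression",
    "make_reference_config",
]


@dataclass
class ToyModel:
    """A small dynamical system with closed-form ground truths.

    Implements the dynamics protocol used across the package (``f``,
    ``names``, ``clamped``, ``x0``) and carries a ``truths`` dict of
    machine-checkable properties.
    """

    name: str
    names: list
    x0: np.ndarray
    drift: object  # callable (m, d) -> (m, d)
    truths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.clamped = np.zeros(len(self.names), bool)

    @property
    def dimension(self) -> int:
        return len(self.names)

    def f(self, X):
        X = np.asarray(X, float)
        single = X.ndim == 1
        out = self.drift(np.atleast_2d(X))
        return out[0] if single else out

    def with_params(self, **kw) -> "ToyModel":
        params = dict(self.params)
        params.update(kw)
        return make_toy(self.name, **params)


def _double_well_1d(**_):
    def drift(X):
        x = X[:, 0]
        return (x - x**3)[:, None]

    return ToyModel(
        name="double_well_1d", names=["x"], x0=np.array([1.0]), drift=drift,
        truths={
            "fixed_points": [-1.0, 1.0], "saddle": 0.0,
            "potential": lambda x: x**4 / 4 - x**2 / 2,
            "barrier_dV": 0.25,
        },
    )


def _double_well_2d(**_):
    def drift(X):
        x, y = X[:, 0], X[:, 1]
        return np.c_[-4 * x * (x**2 - 1), -2 * y]

    return ToyModel(
        name="double_well_2d", names=["x", "y"], x0=np.array([1.0, 0.0]), drift=drift,
        truths={
            "fixed_points": [(-1.0, 0.0), (1.0, 0.0)], "saddle": (0.0, 0.0),
            "potential": lambda x, y: (x**2 - 1) ** 2 + y**2,
            "barrier_dV": 1.0,
            "gradient": True,
        },
    )


def _rotational_linear(omega: float = 1.0, **_):
    def drift(X):
        x, y = X[:, 0], X[:, 1]
        return np.c_[-x + omega * y, -y - omega * x]

    return ToyModel(
        name="rotational_linear", names=["x", "y"], x0=np.array([0.5, 0.0]),
        drift=drift, params={"omega": omega},
        truths={
            # isotropic noise D: stationary N(0, D I); J = omega (y, -x) rho
            "stationary_var": lambda D: D,
            "epr": lambda D: 2.0 * omega**2,  # independent of D
            "flux_zero": omega == 0.0,
            "omega": omega,
        },
    )


def _relaxation_oscillator(mu: float = 2.0, **_):
    def drift(X):
        x, y = X[:, 0], X[:, 1]
        return np.c_[y, mu * (1 - x**2) * y - x]

    return ToyModel(
        name="relaxation_oscillator", names=["x", "y"], x0=np.array([1.0, 0.0]),
        drift=drift, params={"mu": mu},
        truths={"oscillates": True, "mu": mu},
    )


def _bistable_switch(A: float = 1.5, S: float = 0.5, n: int = 4,
                     gamma: float = 0.1, **_):
    def drift(X):
        x, y = X[:, 0], X[:, 1]
        return np.c_[
            A * shifted_hill(np.maximum(y, 0), S, n, gamma) - x,
            A * shifted_hill(np.maximum(x, 0), S, n, gamma) - y,
        ]

    def root_grid(n_grid=400, lim=2.5):
        """Dense-grid root search: the shipped independent oracle."""
        xs = np.linspace(0, lim, n_grid)
        roots = []
        for x in xs:
            # solve y from x's equation, check x's consistency on grid
            y = A * shifted_hill(x, S, n, gamma)
            x_back = A * shifted_hill(y, S, n, gamma)
            if abs(x_back - x) < lim / n_grid:
                roots.append((float(x_back), float(y)))
        # cluster
        out = []
        for r in roots:
            if not any(np.hypot(r[0] - o[0], r[1] - o[1]) < 0.1 for o in out):
                out.append(r)
        return out

    return ToyModel(
        name="bistable_switch", names=["x", "y"], x0=np.array([1.0, 0.1]),
        drift=drift, params={"A": A, "S": S, "n": n, "gamma": gamma},
        truths={"root_oracle": root_grid, "n_stable": 2},
    )


def _saddle_node(r: float = -0.5, **_):
    # fold normal form near the origin with a quartic bound for integrability
    def drift(X):
        x = X[:, 0]
        return (r + x**2 - x**4 / 4)[:, None]

    return ToyModel(
        name="saddle_node", names=["x"], x0=np.array([0.0]), drift=drift,
        params={"r": r},
        truths={"transition_at": 0.0},
    )


def _ou_1d(k: float = 1.0, **_):
    def drift(X):
        return -k * X

    return ToyModel(
        name="ou_1d", names=["x"], x0=np.array([0.0]), drift=drift, params={"k": k},
        truths={"stationary_var": lambda D: D / k},
    )


_REGISTRY = {
    "double_well_1d": _double_well_1d,
    "double_well_2d": _double_well_2d,
    "rotational_linear": _rotational_linear,
    "relaxation_oscillator": _relaxation_oscillator,
    "bistable_switch": _bistable_switch,
    "saddle_node": _saddle_node,
    "ou_1d": _ou_1d,
}


def toy_names() -> list:
    return sorted(_REGISTRY)


def make_toy(name: str, **params) -> ToyModel:
    """Instantiate a registered toy system with its declared truths."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown toy {name!r}; available: {toy_names()}") from None
    return factory(**params)


# ---------------------------------------------------------------------------
# synthetic expression matrices
# ---------------------------------------------------------------------------


@dataclass
class SyntheticExpressionSpec:
    """Four-state expression generator mirroring the metabolic-state geometry.

    Group means per latent state (glycolysis-group mean, OXPHOS-group
    mean): normal low/low, glycolysis high/low, OXPHOS low/high,
    intermediate mid/mid.  Gene-level expression is Gaussian around the
    state's group mean with per-gene noise.
    """

    n_per_state: int = 60
    genes_per_group: int = 20
    noise_sd: float = 1.2
    seed: int = 0
    state_means: dict = field(default_factory=lambda: {
        "normal": (2.0, 2.0),
        "glycolysis": (6.0, 2.5),
        "OXPHOS": (2.5, 6.0),
        "intermediate": (4.2, 4.2),
    })

    def __post_init__(self):
        if self.n_per_state < 1 or self.genes_per_group < 1:
            raise ValueError("counts must be positive")


def make_synthetic_expression(spec: SyntheticExpressionSpec | None = None):
    """Genes x samples matrix plus latent state labels.

    Returns ``(matrix, labels)``: a DataFrame with gene ids GLY_i /
    OXP_i and a Series of latent state names per sample.  Pure function
    of the spec and its seed.
    """
    spec = spec or SyntheticExpressionSpec()
    rng = np.random.default_rng(spec.seed)
    genes = [f"GLY_{i:03d}" for i in range(spec.genes_per_group)] + \
            [f"OXP_{i:03d}" for i in range(spec.genes_per_group)]
    cols, labels, blocks = [], [], []
    # per-gene offsets make genes individual while preserving group structure
    gene_offsets = rng.normal(0, 0.3, size=len(genes))
    for state, (gly_mu, oxp_mu) in spec.state_means.items():
        mu = np.r_[np.full(spec.genes_per_group, gly_mu),
                   np.full(spec.genes_per_group, oxp_mu)] + gene_offsets
        block = rng.normal(mu[:, None], spec.noise_sd,
                           size=(len(genes), spec.n_per_state))
        blocks.append(np.maximum(block, 0.0))
        for k in range(spec.n_per_state):
            cols.append(f"{state[:3].upper()}_{k:03d}")
            labels.append(state)
    matrix = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    return matrix, pd.Series(labels, index=cols, name="latent_state")


def reference_gene_groups() -> tuple:
    """Gene-group id lists matching the synthetic matrix layout."""
    spec = SyntheticExpressionSpec()
    gly = [f"GLY_{i:03d}" for i in range(spec.genes_per_group)]
    oxp = [f"OXP_{i:03d}" for i in range(spec.genes_per_group)]
    return gly, oxp


# ---------------------------------------------------------------------------
# reference-configuration scaffolding
# ---------------------------------------------------------------------------


def make_reference_config(source=None, seed: int | None = None,
                          n_tries: int = 12, min_basins: int = 3):
    """Model configuration tables: transcription or calibration mode.

    With ``source`` set (a directory of nodes/edges/reactions/kinetics
    tables), the tables are read and re-emitted verbatim through the
    assembler (transcription mode).  Otherwise a seeded calibration
    search jitters the shipped interaction strengths (log-normal, 10%)
    and accepts the first draw whose attractor search finds at least
    ``min_basins`` coexisting basins; draw zero is the shipped
    parameter set itself.  All calibrated output is watermarked as
    synthetic.
    """
    from .network import read_model_tables, set_parameter
    from .reference import build_reference_model, reference_sim_config
    from .simulate import find_attractors

    if source is not None:
        model = read_model_tables(source)
        return model
    rng = np.random.default_rng(0 if seed is None else seed)
    base = build_reference_model()
    for attempt in range(n_tries):
        model = base
        if attempt > 0:
            for e in base.edges:
                model = set_parameter(
                    model, f"gamma:{e.source}->{e.target}",
                    float(e.gamma * rng.lognormal(0.0, 0.1)),
                )
        cfg = reference_sim_config(seed=seed or 0)
        ats = find_attractors(model, cfg, projection=("LDH", "PDH"))
        if len(ats) >= min_basins:
            return model
    raise RuntimeError(
        f"calibration failed: no draw with >= {min_basins} basins in {n_tries} tries"
    )
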