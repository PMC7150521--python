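"""Coupled gene-regulatory/metabolic network models.

A model couples two layers with different dynamics:

* gene and enzyme nodes follow production--degradation kinetics,
  ``dX/dt = A * prod_j H(X_j) - D * X``, where each incoming regulation
  contributes a multiplicative shifted-Hill factor ``H`` interpolating
  between 1 (regulator absent) and the fold-change ``gamma`` (regulator
  saturating);
* metabolite nodes follow stoichiometry-signed sums of reaction
  velocities, each velocity scaled by the level of the catalysing
  enzyme, ``dY/dt = sum_j X_j * r_j``.

Models are declarative: four tables (nodes, edges, reactions, kinetics)
fully determine the dynamics.  Rate laws are looked up in a registry so
new kinetic forms are data, not code.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeSpec",
    "GeneKinetics",
    "RegulationEdge",
    "ReactionSpec",
    "NetworkModel",
    "NetworkDynamics",
    "ConfigurationError",
    "shifted_hill",
    "gene_rhs",
    "reaction_velocity",
    "metabolite_rhs",
    "assemble_model",
    "validate_model",
    "register_rate_law",
    "chain_yield",
    "get_parameter",
    "set_parameter",
    "read_model_tables",
    "write_model_tables",
]

ROLES = ("gene", "enzyme", "metabolite")
EDGE_CATEGORIES = ("gene-gene", "gene-enzyme", "metabolite-gene", "metabolite-enzyme")


class ConfigurationError(ValueError):
    """A model table or parameter reference does not resolve."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    id: str
    name: str
    role: str
    clamped: bool = False
    default_initial: float = 0.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(f"node {self.id!r}: unknown role {self.role!r}")
        if not np.isfinite(self.default_initial) or self.default_initial < 0:
            raise ConfigurationError(f"node {self.id!r}: bad default_initial")


@dataclass(frozen=True)
class GeneKinetics:
    A: float  # basal production rate (level / time)
    D: float  # degradation rate (1 / time)

    def __post_init__(self):
        if self.A < 0 or not np.isfinite(self.A):
            raise ConfigurationError(f"production rate A must be >= 0, got {self.A}")
        if self.D <= 0 or not np.isfinite(self.D):
            raise ConfigurationError(f"degradation rate D must be > 0, got {self.D}")


@dataclass(frozen=True)
class RegulationEdge:
    source: str
    target: str
    gamma: float  # fold change: > 1 activation, < 1 inhibition
    S: float  # half-threshold level of the regulator
    n: int  # Hill coefficient
    category: str = ""

    def __post_init__(self):
        if self.gamma <= 0 or not np.isfinite(self.gamma):
            raise ConfigurationError(f"edge {self.key}: gamma must be > 0")
        if self.S <= 0 or not np.isfinite(self.S):
            raise ConfigurationError(f"edge {self.key}: S must be > 0")
        if int(self.n) < 1:
            raise ConfigurationError(f"edge {self.key}: n must be >= 1")

    @property
    def key(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class ReactionSpec:
    id: str
    substrates: tuple  # ((node_id, stoich), ...)
    products: tuple
    enzyme: str | None
    rate_law: str
    kinetic_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, pairs in (("substrate", self.substrates), ("product", self.products)):
            for node, coef in pairs:
                if int(coef) != coef or coef < 1:
                    raise ConfigurationError(
                        f"reaction {self.id!r}: {name} {node!r} stoichiometric "
                        f"coefficient must be a positive integer, got {coef}"
                    )
        for key, val in self.kinetic_params.items():
            if val < 0 or not np.isfinite(val):
                raise ConfigurationError(
                    f"reaction {self.id!r}: kinetic parameter {key!r} must be "
                    f"nonnegative, got {val}"
                )


@dataclass
class NetworkModel:
    nodes: list
    gene_kinetics: dict  # node id -> GeneKinetics
    edges: list
    reactions: list

    def __post_init__(self):
        self._index = {n.id: i for i, n in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            seen, dup = set(), None
            for n in self.nodes:
                if n.id in seen:
                    dup = n.id
                seen.add(n.id)
            raise ConfigurationError(f"duplicate node id {dup!r}")

    # -- lookups ----------------------------------------------------------
    @property
    def node_ids(self) -> list:
        return [n.id for n in self.nodes]

    def node_index(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise ConfigurationError(f"unknown node id {node_id!r}") from None

    def get_node(self, node_id: str) -> NodeSpec:
        return self.nodes[self.node_index(node_id)]

    def nodes_by_role(self, role: str) -> list:
        return [n for n in self.nodes if n.role == role]

    def incoming_edges(self, target: str) -> list:
        return [e for e in self.edges if e.target == target]

    def find_edge(self, source: str, target: str) -> RegulationEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise ConfigurationError(f"no edge {source}->{target} in model")

    def find_reaction(self, rxn_id: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise ConfigurationError(f"no reaction {rxn_id!r} in model")

    @property
    def dimension(self) -> int:
        return len(self.nodes)

    def default_state(self) -> np.ndarray:
        return np.array([n.default_initial for n in self.nodes], float)

    def clamped_mask(self) -> np.ndarray:
        return np.array([n.clamped for n in self.nodes], bool)

    def copy(self) -> "NetworkModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# shifted Hill regulation
# ---------------------------------------------------------------------------


def shifted_hill(x, S: float, n: int, gamma: float):
    """Shifted Hill regulation factor ``S^n/(S^n+x^n) + gamma x^n/(S^n+x^n)``.

    Monotone from 1 at ``x = 0`` to ``gamma`` as ``x -> inf``; ``gamma > 1``
    is activation, ``gamma < 1`` inhibition.  Vectorized in ``x``.
    """
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("regulator level must be finite and nonnegative")
    if not (np.isfinite(S) and S > 0):
        raise ValueError("half-threshold S must be finite and > 0")
    if not (np.isfinite(gamma) and gamma > 0):
        raise ValueError("fold-change gamma must be finite and > 0")
    n = int(n)
    if n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    w = (x / S) ** n
    out = (1.0 + gamma * w) / (1.0 + w)
    return out if out.ndim else float(out)


def _as_state_getter(state, model: NetworkModel | None):
    """Return callable node_id -> level for dict or array states."""
    if isinstance(state, Mapping):
        return lambda nid: state[nid]
    arr = np.asarray(state, float)
    if model is None:
        raise ValueError("array states require the model for index resolution")
    return lambda nid: arr[..., model.node_index(nid)]


def gene_rhs(state, target: str, model: NetworkModel, bias: float = 0.0):
    """Right-hand side for a gene or enzyme node: ``A * prod H - D * x + bias``.

    With no incoming regulation the Hill product is 1.
    """
    node = model.get_node(target)
    if node.role not in ("gene", "enzyme"):
        raise ValueError(f"gene_rhs applies to gene/enzyme nodes, {target!r} is a {node.role}")
    kin = model.gene_kinetics[target]
    get = _as_state_getter(state, model)
    prod = 1.0
    for e in model.incoming_edges(target):
        prod = prod * shifted_hill(get(e.source), e.S, e.n, e.gamma)
    return kin.A * prod - kin.D * get(target) + bias


# ---------------------------------------------------------------------------
# rate-law registry
# ---------------------------------------------------------------------------

_RATE_LAWS: dict = {}


def register_rate_law(name: str, fn: Callable) -> None:
    """Register ``fn(reaction, get) -> velocity`` under ``name``.

    ``get`` maps a node id to its (possibly vectorized) level.
    """
    _RATE_LAWS[name] = fn


def _law_mass_action(rxn: ReactionSpec, get):
    v = rxn.kinetic_params["k"]
    for node, coef in rxn.substrates:
        v = v * get(node) ** coef
    return v


def _mm_core(rxn: ReactionSpec, get):
    v = rxn.kinetic_params["vmax"]
    for node, _coef in rxn.substrates:
        km = rxn.kinetic_params.get(f"km_{node}", rxn.kinetic_params.get("km"))
        if km is None:
            raise ConfigurationError(
                f"reaction {rxn.id!r}: missing km (or km_{node}) parameter"
            )
        s = get(node)
        v = v * s / (km + s)
    return v


def _law_michaelis_menten(rxn: ReactionSpec, get):
    return _mm_core(rxn, get)


def _law_mm_modulated(rxn: ReactionSpec, get):
    """Irreversible Michaelis-Menten times saturating activator/inhibitor factors.

    Modifiers are encoded in the kinetic parameters as ``act_<node> = K``
    (factor ``x/(K+x)``) and ``inh_<node> = K`` (factor ``K/(K+x)``).
    """
    v = _mm_core(rxn, get)
    for key, K in rxn.kinetic_params.items():
        if key.startswith("act_"):
            x = get(key[4:])
            v = v * x / (K + x)
        elif key.startswith("inh_"):
            x = get(key[4:])
            v = v * K / (K + x)
    return v


register_rate_law("mass_action", _law_mass_action)
register_rate_law("michaelis_menten", _law_michaelis_menten)
register_rate_law("mm_modulated", _law_mm_modulated)


def reaction_velocity(rxn: ReactionSpec, state, model: NetworkModel | None = None):
    """Evaluate the kinetic velocity ``r_j`` at the current metabolite levels.

    The returned velocity excludes the enzyme-level factor; the enzyme
    multiplies the contribution in :func:`metabolite_rhs`.
    """
    try:
        law = _RATE_LAWS[rxn.rate_law]
    except KeyError:
        raise ConfigurationError(
            f"reaction {rxn.id!r}: unknown rate law {rxn.rate_law!r}"
        ) from None
    get = _as_state_getter(state, model)
    for node, _coef in rxn.substrates:
        val = np.asarray(get(node), float)
        if np.any(val < 0) or not np.all(np.isfinite(val)):
            raise ValueError(f"negative or non-finite concentration for {node!r}")
    return law(rxn, get)


def metabolite_rhs(state, target: str, model: NetworkModel):
    """Signed sum of enzyme-scaled reaction velocities for one metabolite.

    Clamped metabolites (boundary conditions such as O2) return 0.
    """
    node = model.get_node(target)
    if node.role != "metabolite":
        raise ValueError(f"metabolite_rhs applies to metabolites, {target!r} is a {node.role}")
    if node.clamped:
        return 0.0
    get = _as_state_getter(state, model)
    total = 0.0
    for rxn in model.reactions:
        stoich = 0
        for nid, coef in rxn.substrates:
            if nid == target:
                stoich -= coef
        for nid, coef in rxn.products:
            if nid == target:
                stoich += coef
        if stoich == 0:
            continue
        v = reaction_velocity(rxn, state, model)
        enz = get(rxn.enzyme) if rxn.enzyme else 1.0
        total = total + stoich * enz * v
    return total


# ---------------------------------------------------------------------------
# vectorized dynamics
# ---------------------------------------------------------------------------


class NetworkDynamics:
    """Vectorized right-hand side of a :class:`NetworkModel`.

    Evaluates the drift for an ensemble of states at once, which is what
    the stochastic integrators rely on for throughput.  ``biases`` maps
    node ids to additive constants (the therapeutic ``F + c`` deformation).
    """

    def __init__(self, model: NetworkModel, biases: Mapping[str, float] | None = None):
        self.model = model
        self.names = model.node_ids
        self.clamped = model.clamped_mask()
        self.x0 = model.default_state()
        n = model.dimension
        idx = model.node_index

        ge = [m for m in model.nodes if m.role in ("gene", "enzyme")]
        self._ge_idx = np.array([idx(m.id) for m in ge], int)
        self._A = np.array([model.gene_kinetics[m.id].A for m in ge], float)
        self._D = np.array([model.gene_kinetics[m.id].D for m in ge], float)
        self._edges = [
            (idx(e.source), idx(e.target), float(e.S) ** int(e.n), int(e.n), float(e.gamma))
            for e in model.edges
        ]
        self._reactions = []
        for r in model.reactions:
            subs = [(idx(nid), int(c)) for nid, c in r.substrates]
            prods = [(idx(nid), int(c)) for nid, c in r.products]
            enz = idx(r.enzyme) if r.enzyme else -1
            self._reactions.append((r, subs, prods, enz))
        self.nonnegative = True
        self.bias = np.zeros(n)
        if biases:
            for nid, c in biases.items():
                node = model.get_node(nid)
                if node.role == "metabolite":
                    raise ValueError(
                        f"constant-force interventions target genes/enzymes, not {nid!r}"
                    )
                self.bias[idx(nid)] = c

    @property
    def dimension(self) -> int:
        return len(self.names)

    def node_index(self, node_id: str) -> int:
        return self.model.node_index(node_id)

    def f(self, X: np.ndarray) -> np.ndarray:
        """Drift for states ``X`` of shape (m, n) or (n,)."""
        X = np.asarray(X, float)
        single = X.ndim == 1
        if single:
            X = X[None]
        m, n = X.shape
        prod = np.ones((m, n))
        for src, tgt, Sn, hill_n, gamma in self._edges:
            xn = X[:, src] ** hill_n
            prod[:, tgt] *= (Sn + gamma * xn) / (Sn + xn)
        dX = np.zeros_like(X)
        dX[:, self._ge_idx] = self._A * prod[:, self._ge_idx] - self._D * X[:, self._ge_idx]
        if self._reactions:
            get = lambda nid: X[:, self.model.node_index(nid)]  # noqa: E731
            for r, subs, prods, enz in self._reactions:
                v = _RATE_LAWS[r.rate_law](r, get)
                if enz >= 0:
                    v = v * X[:, enz]
                for i, c in subs:
                    dX[:, i] -= c * v
                for i, c in prods:
                    dX[:, i] += c * v
        dX += self.bias
        dX[:, self.clamped] = 0.0
        return dX[0] if single else dX


# ---------------------------------------------------------------------------
# assembly from tables
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y"}


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in _TRUTHY
    return bool(v)


def _parse_pairs(cell) -> tuple:
    """Parse ``"Glc:1;ATP:1"`` into ((node, coef), ...); empty cell -> ()."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return ()
    out = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        nid, _, coef = part.partition(":")
        out.append((nid.strip(), int(coef) if coef else 1))
    return tuple(out)


def _infer_category(model_roles: Mapping[str, str], source: str, target: str) -> str:
    src = "gene" if model_roles[source] in ("gene", "enzyme") else "metabolite"
    tgt = model_roles[target]
    if tgt == "metabolite":
        raise ConfigurationError(f"edge {source}->{target}: target may not be a metabolite")
    return f"{src}-{tgt}"


def assemble_model(node_table, edge_table, reaction_table, kinetics_table) -> NetworkModel:
    """Build a validated :class:`NetworkModel` from four tables.

    Tables may be DataFrames or paths to tab-separated files.  The
    kinetics table has columns (kind, target, param, value) with kind
    ``gene`` (params A, D keyed by node id) or ``reaction`` (rate-law
    parameters keyed by reaction id).
    """
    nodes_df, edges_df, rxn_df, kin_df = (
        pd.read_csv(t, sep="\t", comment="#") if not isinstance(t, pd.DataFrame) else t
        for t in (node_table, edge_table, reaction_table, kinetics_table)
    )

    nodes = []
    for _, row in nodes_df.iterrows():
        nodes.append(
            NodeSpec(
                id=str(row["id"]),
                name=str(row.get("name", row["id"])),
                role=str(row["role"]),
                clamped=_as_bool(row.get("clamped", False)),
                default_initial=float(row.get("default_initial", 0.0)),
            )
        )
    roles = {n.id: n.role for n in nodes}
    if len(roles) != len(nodes):
        raise ConfigurationError("duplicate node ids in node table")

    gene_params: dict = {}
    rxn_params: dict = {}
    for _, row in kin_df.iterrows():
        kind, target, param, value = (
            str(row["kind"]),
            str(row["target"]),
            str(row["param"]),
            float(row["value"]),
        )
        if kind == "gene":
            if target not in roles:
                raise ConfigurationError(f"kinetics row targets unknown node {target!r}")
            gene_params.setdefault(target, {})[param] = value
        elif kind == "reaction":
            rxn_params.setdefault(target, {})[param] = value
        else:
            raise ConfigurationError(f"kinetics row has unknown kind {kind!r}")

    gene_kinetics = {}
    for n in nodes:
        if n.role in ("gene", "enzyme"):
            p = gene_params.get(n.id)
            if p is None or "A" not in p or "D" not in p:
                raise ConfigurationError(f"node {n.id!r}: missing gene kinetics (A, D)")
            gene_kinetics[n.id] = GeneKinetics(A=p["A"], D=p["D"])

    edges = []
    for _, row in edges_df.iterrows():
        src, tgt = str(row["source"]), str(row["target"])
        for nid in (src, tgt):
            if nid not in roles:
                raise ConfigurationError(f"edge {src}->{tgt} references unknown node {nid!r}")
        category = str(row["category"]) if "category" in row and pd.notna(row.get("category")) else ""
        inferred = _infer_category(roles, src, tgt)
        if category and category != inferred:
            raise ConfigurationError(
                f"edge {src}->{tgt}: declared category {category!r} does not match roles"
            )
        edges.append(
            RegulationEdge(
                source=src,
                target=tgt,
                gamma=float(row["gamma"]),
                S=float(row["S"]),
                n=int(row["n"]),
                category=inferred,
            )
        )
    if len({(e.source, e.target) for e in edges}) != len(edges):
        raise ConfigurationError("duplicate edge in edge table")

    reactions = []
    for _, row in rxn_df.iterrows():
        rid = str(row["id"])
        enzyme = row.get("enzyme")
        enzyme = None if enzyme is None or (isinstance(enzyme, float) and math.isnan(enzyme)) or str(enzyme).strip() in ("", "-") else str(enzyme)
        rxn = ReactionSpec(
            id=rid,
            substrates=_parse_pairs(row.get("substrates")),
            products=_parse_pairs(row.get("products")),
            enzyme=enzyme,
            rate_law=str(row["rate_law"]),
            kinetic_params=rxn_params.get(rid, {}),
        )
        for nid, _c in rxn.substrates + rxn.products:
            if nid not in roles:
                raise ConfigurationError(f"reaction {rid!r} references unknown node {nid!r}")
        if rxn.enzyme is not None:
            if rxn.enzyme not in roles:
                raise ConfigurationError(f"reaction {rid!r}: unknown enzyme {rxn.enzyme!r}")
            if roles[rxn.enzyme] == "metabolite":
                raise ConfigurationError(f"reaction {rid!r}: enzyme {rxn.enzyme!r} is a metabolite")
        if rxn.rate_law not in _RATE_LAWS:
            raise ConfigurationError(f"reaction {rid!r}: unknown rate law {rxn.rate_law!r}")
        reactions.append(rxn)
    if len({r.id for r in reactions}) != len(reactions):
        raise ConfigurationError("duplicate reaction id in reaction table")

    return NetworkModel(nodes=nodes, gene_kinetics=gene_kinetics, edges=edges, reactions=reactions)


def write_model_tables(model: NetworkModel, directory, header_note: str | None = None) -> None:
    """Write the four model tables to ``directory`` (nodes/edges/reactions/kinetics .tsv)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = f"# {header_note}\n" if header_note else ""

    def _dump(df, name):
        path = directory / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(prefix)
            df.to_csv(fh, sep="\t", index=False)

    _dump(
        pd.DataFrame(
            [
                {
                    "id": n.id,
                    "name": n.name,
                    "role": n.role,
                    "clamped": int(n.clamped),
                    "default_initial": n.default_initial,
                }
                for n in model.nodes
            ]
        ),
        "nodes",
    )
    _dump(
        pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "gamma": e.gamma,
                    "S": e.S,
                    "n": e.n,
                    "category": e.category,
                }
                for e in model.edges
            ]
        ),
        "edges",
    )
    _dump(
        pd.DataFrame(
            [
                {
                    "id": r.id,
                    "substrates": ";".join(f"{n}:{c}" for n, c in r.substrates),
                    "products": ";".join(f"{n}:{c}" for n, c in r.products),
                    "enzyme": r.enzyme or "",
                    "rate_law": r.rate_law,
                }
                for r in model.reactions
            ]
        ),
        "reactions",
    )
    kin_rows = []
    for nid, k in model.gene_kinetics.items():
        kin_rows.append({"kind": "gene", "target": nid, "param": "A", "value": k.A})
        kin_rows.append({"kind": "gene", "target": nid, "param": "D", "value": k.D})
    for r in model.reactions:
        for p, v in r.kinetic_params.items():
            kin_rows.append({"kind": "reaction", "target": r.id, "param": p, "value": v})
    _dump(pd.DataFrame(kin_rows), "kinetics")


def read_model_tables(directory) -> NetworkModel:
    from pathlib import Path

    d = Path(directory)
    return assemble_model(
        d / "nodes.tsv", d / "edges.tsv", d / "reactions.tsv", d / "kinetics.tsv"
    )


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------


def chain_yield(model: NetworkModel, chain: Sequence[str], start: str, targets: Sequence[str]) -> dict:
    """Net production of ``targets`` per unit of ``start`` through a reaction chain.

    Propagates stoichiometric multiplicity: each reaction in ``chain``
    runs as many times as its chain substrate has been produced so far
    (e.g. the aldolase split doubles the flux through lower glycolysis).
    """
    avail = {start: 1.0}
    net = {t: 0.0 for t in targets}
    for rid in chain:
        rxn = model.find_reaction(rid)
        carrier = None
        for nid, coef in rxn.substrates:
            if nid in avail and avail[nid] > 0:
                carrier = (nid, coef)
                break
        if carrier is None:
            raise ConfigurationError(
                f"chain reaction {rid!r} has no available substrate from the chain"
            )
        runs = avail[carrier[0]] / carrier[1]
        avail[carrier[0]] = 0.0
        for nid, coef in rxn.products:
            avail[nid] = avail.get(nid, 0.0) + coef * runs
        for t in targets:
            for nid, coef in rxn.substrates:
                if nid == t:
                    net[t] -= coef * runs
            for nid, coef in rxn.products:
                if nid == t:
                    net[t] += coef * runs
    return net


@dataclass
class ValidationReport:
    node_counts: dict
    edge_counts: dict
    n_nodes: int
    n_edges: int
    n_reactions: int
    reactions_missing_kinetics: list
    chain_yields: dict

    def as_dict(self) -> dict:
        out = {f"nodes_{k}": v for k, v in self.node_counts.items()}
        out.update({f"edges_{k}": v for k, v in self.edge_counts.items()})
        out.update(
            n_nodes=self.n_nodes,
            n_edges=self.n_edges,
            n_reactions=self.n_reactions,
            reactions_missing_kinetics=list(self.reactions_missing_kinetics),
        )
        for chain_name, yields in self.chain_yields.items():
            for t, v in yields.items():
                out[f"{chain_name}_net_{t}"] = v
        return out

    def __str__(self) -> str:
        lines = [f"{k}\t{v}" for k, v in self.as_dict().items()]
        return "\n".join(lines)


def validate_model(model: NetworkModel, chains: Mapping[str, dict] | None = None) -> ValidationReport:
    """Report-only structural validation.

    ``chains`` optionally maps a name to ``{"reactions": [...], "start":
    node, "targets": [...]}`` for stoichiometric path sums (e.g. net
    pyruvate and ATP per glucose through glycolysis).
    """
    node_counts = {role: len(model.nodes_by_role(role)) for role in ROLES}
    edge_counts = {cat: 0 for cat in EDGE_CATEGORIES}
    for e in model.edges:
        edge_counts[e.category] = edge_counts.get(e.category, 0) + 1
    missing = []
    for r in model.reactions:
        try:
            probe = {nid: 1.0 for nid in model.node_ids}
            reaction_velocity(r, probe)
        except (ConfigurationError, KeyError):
            missing.append(r.id)
    chain_yields = {}
    for name, ch in (chains or {}).items():
        chain_yields[name] = chain_yield(model, ch["reactions"], ch["start"], ch["targets"])
    return ValidationReport(
        node_counts=node_counts,
        edge_counts=edge_counts,
        n_nodes=model.dimension,
        n_edges=len(model.edges),
        n_reactions=len(model.reactions),
        reactions_missing_kinetics=missing,
        chain_yields=chain_yields,
    )


# ---------------------------------------------------------------------------
# parameter paths
# ---------------------------------------------------------------------------


def _resolve_path(model: NetworkModel, path: str):
    parts = path.split(":")
    kind = parts[0]
    if kind in ("gamma", "S", "n") and len(parts) == 2 and "->" in parts[1]:
        src, _, tgt = parts[1].partition("->")
        return ("edge", kind, src, tgt)
    if kind in ("A", "D") and len(parts) == 2:
        return ("gene", kind, parts[1])
    if kind in ("clamp", "init") and len(parts) == 2:
        return ("node", kind, parts[1])
    if kind == "kin" and len(parts) == 3:
        return ("reaction", parts[1], parts[2])
    raise ConfigurationError(f"cannot parse parameter path {path!r}")


def get_parameter(model: NetworkModel, path: str) -> float:
    ref = _resolve_path(model, path)
    if ref[0] == "edge":
        return float(getattr(model.find_edge(ref[2], ref[3]), ref[1]))
    if ref[0] == "gene":
        nid = ref[2]
        if nid not in model.gene_kinetics:
            raise ConfigurationError(f"node {nid!r} has no gene kinetics")
        return float(getattr(model.gene_kinetics[nid], ref[1]))
    if ref[0] == "node":
        return float(model.get_node(ref[2]).default_initial)
    rxn = model.find_reaction(ref[1])
    try:
        return float(rxn.kinetic_params[ref[2]])
    except KeyError:
        raise ConfigurationError(f"reaction {ref[1]!r} has no parameter {ref[2]!r}") from None


def set_parameter(model: NetworkModel, path: str, value: float) -> NetworkModel:
    """Return a copy of ``model`` with one scalar parameter replaced."""
    ref = _resolve_path(model, path)
    new = model.copy()
    if ref[0] == "edge":
        e = new.find_edge(ref[2], ref[3])
        i = new.edges.index(e)
        kwargs = {"source": e.source, "target": e.target, "gamma": e.gamma, "S": e.S,
                  "n": e.n, "category": e.category}
        kwargs[ref[1]] = int(value) if ref[1] == "n" else float(value)
        new.edges[i] = RegulationEdge(**kwargs)
        return new
    if ref[0] == "gene":
        nid = ref[2]
        if nid not in new.gene_kinetics:
            raise ConfigurationError(f"node {nid!r} has no gene kinetics")
        k = new.gene_kinetics[nid]
        new.gene_kinetics[nid] = GeneKinetics(
            A=float(value) if ref[1] == "A" else k.A,
            D=float(value) if ref[1] == "D" else k.D,
        )
        return new
    if ref[0] == "node":
        i = new.node_index(ref[2])
        n = new.nodes[i]
        if ref[1] == "clamp" and not n.clamped:
            raise ConfigurationError(f"node {ref[2]!r} is not clamped")
        new.nodes[i] = NodeSpec(
            id=n.id, name=n.name, role=n.role, clamped=n.clamped, default_initial=float(value)
        )
        return new
    rxn = new.find_reaction(ref[1])
    if ref[2] not in rxn.kinetic_params:
        raise ConfigurationError(f"reaction {ref[1]!r} has no parameter {ref[2]!r}")
    i = new.reactions.index(rxn)
    params = dict(rxn.kinetic_params)
    params[ref[2]] = float(value)
    new.reactions[i] = ReactionSpec(
        id=rxn.id, substrates=rxn.substrates, products=rxn.products,
        enzyme=rxn.enzyme, rate_law=rxn.rate_law, kinetic_params=params,
    )
    return new
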