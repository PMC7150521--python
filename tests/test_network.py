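"""Unit and property tests for the network model layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxscape.network import (
    ConfigurationError,
    NetworkDynamics,
    assemble_model,
    chain_yield,
    gene_rhs,
    get_parameter,
    metabolite_rhs,
    reaction_velocity,
    register_rate_law,
    set_parameter,
    shifted_hill,
    validate_model,
)
from fluxscape.reference import REFERENCE_CHAINS, build_reference_model, reference_tables


# ---------------------------------------------------------------------------
# shifted Hill function
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, S, n, gamma, expected",
    [
        (0.0, 1.0, 4, 0.1, 1.0),  # no regulator: factor 1
        (1.0, 1.0, 4, 0.1, (1 + 0.1) / 2),  # at threshold: midpoint
        (2.5, 0.7, 3, 1.0, 1.0),  # gamma = 1 collapses to 1
        (1e4, 1.0, 4, 3.0, 3.0),  # saturation approaches gamma
    ],
)
def test_shifted_hill_reference_values(x, S, n, gamma, expected):
    assert shifted_hill(x, S, n, gamma) == pytest.approx(expected, rel=1e-6)


@given(
    x=st.floats(0.0, 50.0),
    S=st.floats(0.05, 5.0),
    n=st.integers(1, 8),
    gamma=st.floats(0.05, 10.0),
)
@settings(max_examples=200, deadline=None)
def test_shifted_hill_three_algebraic_forms_agree(x, S, n, gamma):
    """The sum-of-two-Hills form equals both single-term rearrangements."""
    w = x**n / (S**n + x**n)
    form_sum = S**n / (S**n + x**n) + gamma * w
    form_act = (gamma - 1.0) * w + 1.0
    form_inh = (1.0 - gamma) * (S**n / (S**n + x**n)) + gamma
    h = shifted_hill(x, S, n, gamma)
    assert h == pytest.approx(form_sum, abs=1e-12, rel=1e-9)
    assert h == pytest.approx(form_act, abs=1e-12, rel=1e-9)
    assert h == pytest.approx(form_inh, abs=1e-12, rel=1e-9)
    assert min(1.0, gamma) - 1e-12 <= h <= max(1.0, gamma) + 1e-12


@given(S=st.floats(0.2, 2.0), n=st.integers(1, 6), gamma=st.floats(0.05, 8.0))
@settings(max_examples=60, deadline=None)
def test_shifted_hill_monotonicity(S, n, gamma):
    xs = np.linspace(0, 10 * S, 200)
    h = shifted_hill(xs, S, n, gamma)
    d = np.diff(h)
    if gamma > 1:
        assert np.all(d >= -1e-12)
    elif gamma < 1:
        assert np.all(d <= 1e-12)
    else:
        assert np.allclose(h, 1.0)


def test_shifted_hill_rejects_bad_inputs():
    with pytest.raises(ValueError):
        shifted_hill(-0.1, 1.0, 4, 2.0)
    with pytest.raises(ValueError):
        shifted_hill(1.0, -1.0, 4, 2.0)
    with pytest.raises(ValueError):
        shifted_hill(np.inf, 1.0, 4, 2.0)
    with pytest.raises(ValueError):
        shifted_hill(1.0, 1.0, 0, 2.0)


# ---------------------------------------------------------------------------
# tiny hand-built model
# ---------------------------------------------------------------------------


def _tiny_tables():
    nodes = pd.DataFrame([
        {"id": "g1", "name": "gene 1", "role": "gene", "clamped": 0, "default_initial": 0.5},
        {"id": "g2", "name": "gene 2", "role": "gene", "clamped": 0, "default_initial": 0.5},
        {"id": "E", "name": "enzyme", "role": "enzyme", "clamped": 0, "default_initial": 0.5},
        {"id": "S", "name": "substrate", "role": "metabolite", "clamped": 0, "default_initial": 1.0},
        {"id": "Prod", "name": "product", "role": "metabolite", "clamped": 0, "default_initial": 0.0},
        {"id": "B", "name": "boundary", "role": "metabolite", "clamped": 1, "default_initial": 0.2},
    ])
    edges = pd.DataFrame([
        {"source": "g1", "target": "g2", "gamma": 3.0, "S": 1.0, "n": 4},
        {"source": "S", "target": "g1", "gamma": 0.5, "S": 0.5, "n": 2},
    ])
    reactions = pd.DataFrame([
        {"id": "r1", "substrates": "S:1", "products": "Prod:1", "enzyme": "E",
         "rate_law": "michaelis_menten"},
        {"id": "r2", "substrates": "Prod:1", "products": "", "enzyme": "",
         "rate_law": "mass_action"},
    ])
    kinetics = pd.DataFrame([
        {"kind": "gene", "target": "g1", "param": "A", "value": 2.0},
        {"kind": "gene", "target": "g1", "param": "D", "value": 1.0},
        {"kind": "gene", "target": "g2", "param": "A", "value": 1.0},
        {"kind": "gene", "target": "g2", "param": "D", "value": 1.0},
        {"kind": "gene", "target": "E", "param": "A", "value": 1.0},
        {"kind": "gene", "target": "E", "param": "D", "value": 0.5},
        {"kind": "reaction", "target": "r1", "param": "vmax", "value": 2.0},
        {"kind": "reaction", "target": "r1", "param": "km", "value": 0.5},
        {"kind": "reaction", "target": "r2", "param": "k", "value": 2.0},
    ])
    return nodes, edges, reactions, kinetics


@pytest.fixture
def tiny_model():
    return assemble_model(*_tiny_tables())


def test_gene_rhs_hand_values(tiny_model):
    # unregulated enzyme at steady state A/D
    assert gene_rhs({n: 0 for n in tiny_model.node_ids} | {"E": 2.0}, "E", tiny_model) == \
        pytest.approx(0.0)
    # one activator at its half-threshold: H = (1 + gamma) / 2
    state = {n: 0.0 for n in tiny_model.node_ids}
    state["g1"] = 1.0
    assert gene_rhs(state, "g2", tiny_model) == pytest.approx(1.0 * (1 + 3) / 2)
    with pytest.raises(ValueError):
        gene_rhs(state, "S", tiny_model)


def test_reaction_velocity_laws(tiny_model):
    r1 = tiny_model.find_reaction("r1")
    # substrate at km: half-maximal velocity
    assert reaction_velocity(r1, {"S": 0.5}) == pytest.approx(1.0)
    assert reaction_velocity(r1, {"S": 0.0}) == pytest.approx(0.0)
    r2 = tiny_model.find_reaction("r2")
    assert reaction_velocity(r2, {"Prod": 3.0}) == pytest.approx(6.0)
    with pytest.raises(ValueError):
        reaction_velocity(r1, {"S": -1.0})


def test_metabolite_rhs_signed_sum(tiny_model):
    state = {n: 0.0 for n in tiny_model.node_ids}
    state.update({"S": 0.5, "E": 2.0, "Prod": 1.0})
    # production E * vmax/2 = 2, consumption k * Prod = 2
    assert metabolite_rhs(state, "Prod", tiny_model) == pytest.approx(2.0 - 2.0)
    # clamped boundary metabolite never moves
    assert metabolite_rhs(state, "B", tiny_model) == 0.0
    # metabolite in no reactions
    state2 = dict(state, B=0.2)
    assert metabolite_rhs(state2, "B", tiny_model) == 0.0
    with pytest.raises(ValueError):
        metabolite_rhs(state, "g1", tiny_model)


def test_vectorized_dynamics_matches_per_node(tiny_model):
    dyn = NetworkDynamics(tiny_model)
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 2, size=(5, tiny_model.dimension))
    F = dyn.f(X)
    for row in range(5):
        state = {nid: X[row, i] for i, nid in enumerate(tiny_model.node_ids)}
        for nid in tiny_model.node_ids:
            node = tiny_model.get_node(nid)
            i = tiny_model.node_index(nid)
            if node.role == "metabolite":
                expected = metabolite_rhs(state, nid, tiny_model)
            else:
                expected = gene_rhs(state, nid, tiny_model)
            if node.clamped:
                expected = 0.0
            assert F[row, i] == pytest.approx(expected, abs=1e-10)


def test_assembly_errors():
    nodes, edges, reactions, kinetics = _tiny_tables()
    bad_edges = pd.concat(
        [edges, pd.DataFrame([{"source": "nope", "target": "g1", "gamma": 2.0,
                               "S": 1.0, "n": 2}])]
    )
    with pytest.raises(ConfigurationError):
        assemble_model(nodes, bad_edges, reactions, kinetics)
    bad_kin = kinetics[kinetics.target != "g2"]
    with pytest.raises(ConfigurationError):
        assemble_model(nodes, edges, reactions, bad_kin)
    dup_nodes = pd.concat([nodes, nodes.iloc[[0]]])
    with pytest.raises(ConfigurationError):
        assemble_model(dup_nodes, edges, reactions, kinetics)


def test_single_node_model_and_empty_tables():
    nodes = pd.DataFrame([{"id": "g", "name": "g", "role": "gene", "clamped": 0,
                           "default_initial": 1.0}])
    empty = pd.DataFrame(columns=["source", "target", "gamma", "S", "n"])
    empty_r = pd.DataFrame(columns=["id", "substrates", "products", "enzyme", "rate_law"])
    kin = pd.DataFrame([
        {"kind": "gene", "target": "g", "param": "A", "value": 1.0},
        {"kind": "gene", "target": "g", "param": "D", "value": 1.0},
    ])
    model = assemble_model(nodes, empty, empty_r, kin)
    assert model.dimension == 1 and len(model.edges) == 0
    rep = validate_model(model)
    assert rep.node_counts == {"gene": 1, "enzyme": 0, "metabolite": 0}


def test_custom_rate_law_registration(tiny_model):
    register_rate_law("linear_test", lambda rxn, get: rxn.kinetic_params["k"] *
                      get(rxn.substrates[0][0]))
    from fluxscape.network import ReactionSpec

    rxn = ReactionSpec(id="rx", substrates=(("S", 1),), products=(("Prod", 1),),
                       enzyme=None, rate_law="linear_test", kinetic_params={"k": 3.0})
    assert reaction_velocity(rxn, {"S": 2.0}) == pytest.approx(6.0)
    bad = ReactionSpec(id="rx2", substrates=(("S", 1),), products=(),
                       enzyme=None, rate_law="no_such_law")
    with pytest.raises(ConfigurationError):
        reaction_velocity(bad, {"S": 1.0})


def test_parameter_paths_roundtrip(tiny_model):
    assert get_parameter(tiny_model, "gamma:g1->g2") == 3.0
    m2 = set_parameter(tiny_model, "gamma:g1->g2", 5.0)
    assert get_parameter(m2, "gamma:g1->g2") == 5.0
    assert get_parameter(tiny_model, "gamma:g1->g2") == 3.0  # original untouched
    m3 = set_parameter(tiny_model, "A:g1", 4.0)
    assert get_parameter(m3, "A:g1") == 4.0
    m4 = set_parameter(tiny_model, "kin:r1:vmax", 9.0)
    assert get_parameter(m4, "kin:r1:vmax") == 9.0
    with pytest.raises(ConfigurationError):
        set_parameter(tiny_model, "gamma:g1->nope", 1.0)
    with pytest.raises(ConfigurationError):
        get_parameter(tiny_model, "weird:path")


# ---------------------------------------------------------------------------
# reference configuration
# ---------------------------------------------------------------------------


def test_reference_structure_counts(reference_model):
    rep = validate_model(reference_model, chains=REFERENCE_CHAINS)
    assert rep.n_nodes == 53
    assert rep.node_counts == {"gene": 13, "enzyme": 17, "metabolite": 23}
    assert rep.n_edges == 73
    assert rep.edge_counts["gene-gene"] == 32
    assert not rep.reactions_missing_kinetics


def test_reference_glycolysis_stoichiometry(reference_model):
    yields = chain_yield(
        reference_model, REFERENCE_CHAINS["glycolysis"]["reactions"],
        "Glc_ex", ["Pyr", "ATP"],
    )
    assert yields["Pyr"] == pytest.approx(2.0)
    assert yields["ATP"] == pytest.approx(2.0)


def test_reference_tables_roundtrip(tmp_path, reference_model):
    from fluxscape.network import read_model_tables, write_model_tables

    write_model_tables(reference_model, tmp_path, header_note="synthetic parameters")
    model2 = read_model_tables(tmp_path)
    assert model2.node_ids == reference_model.node_ids
    assert len(model2.edges) == len(reference_model.edges)
    dyn1 = NetworkDynamics(reference_model)
    dyn2 = NetworkDynamics(model2)
    x = reference_model.default_state()
    np.testing.assert_allclose(dyn1.f(x), dyn2.f(x), rtol=1e-12)


def test_reference_rhs_finite_on_random_states(reference_model, rng):
    dyn = NetworkDynamics(reference_model)
    X = rng.uniform(0, 5, size=(50, reference_model.dimension))
    F = dyn.f(X)
    assert np.all(np.isfinite(F))


def test_isolated_gene_fixed_point():
    nodes = pd.DataFrame([{"id": "g", "name": "g", "role": "gene", "clamped": 0,
                           "default_initial": 0.0}])
    kin = pd.DataFrame([
        {"kind": "gene", "target": "g", "param": "A", "value": 2.0},
        {"kind": "gene", "target": "g", "param": "D", "value": 0.5},
    ])
    empty = pd.DataFrame(columns=["source", "target", "gamma", "S", "n"])
    empty_r = pd.DataFrame(columns=["id", "substrates", "products", "enzyme", "rate_law"])
    model = assemble_model(nodes, empty, empty_r, kin)
    from fluxscape.simulate import SimulationConfig, integrate_deterministic

    for x0 in (0.0, 1.0, 10.0):
        traj = integrate_deterministic(model, np.array([x0]),
                                       SimulationConfig(step=0.1, horizon=40.0))
        assert traj.final[0] == pytest.approx(2.0 / 0.5, rel=1e-4)
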