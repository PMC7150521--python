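"""Shipped reference configuration: a 53-node cancer gene-metabolism network.

The wiring couples a 13-gene regulatory layer (PI3K/Akt/mTOR growth
signalling, the HIF-1 / p53 antagonism, AMPK energy sensing, the
VEGF-SOD-ROS axis) to glycolysis, the TCA cycle/oxidative
phosphorylation and their branch pathways through 17 enzymes and 23
metabolites (73 regulatory interactions in total, 32 of them
gene-gene).  Sequential metabolic steps are lumped into comprehensive
reactions (e.g. pyruvate -> citrate stands for pyruvate dehydrogenase
plus citrate synthase), and boundary species (extracellular glucose and
lactate, O2) are clamped nodes whose levels act as scan parameters.

All numeric parameter values here are synthetic: they were calibrated
in-house so that the baseline network is quadristable with the
normal / intermediate / OXPHOS / glycolysis (LDH, PDH) signature and
develops a limit cycle at strong VEGF->SOD regulation.  They are not
transcribed from any publication.
"""

from __future__ import annotations

import pandas as pd

from .network import NetworkModel, assemble_model, set_parameter

__all__ = [
    "build_reference_model",
    "reference_tables",
    "GLYCOLYSIS_CHAIN",
    "REFERENCE_CHAINS",
    "PROJECTION_AXES",
    "OSCILLATORY_GAMMA_VEGF_SOD",
    "WATERMARK",
]

WATERMARK = (
    "synthetic calibrated parameters (quadristability + oscillatory regime); "
    "not transcribed from any publication"
)

PROJECTION_AXES = ("LDH", "PDH")

#: VEGF->SOD fold-change at which the reference network oscillates.
OSCILLATORY_GAMMA_VEGF_SOD = 8.0

#: Oscillatory-regime calibration: parameter-path overrides applied on top of
#: the baseline tables.  The quadristable toggle is recast as a relaxation
#: oscillator: HIF-1 becomes a slow energy-driven integrator (small D, strong
#: ATP->mTOR->HIF-1 arm, weak self-activation) while strong VEGF->SOD->p53
#: drive makes the p53 branch excitable.  The resulting deterministic limit
#: cycle visits the normal, OXPHOS, and glycolysis neighbourhoods clockwise
#: in the (LDH, PDH) plane, and the glycolysis->OXPHOS leg (through the
#: normal corner) is much slower than the return leg.
OSCILLATORY_OVERRIDES = {
    "gamma:VEGF->SOD": OSCILLATORY_GAMMA_VEGF_SOD,
    "S:VEGF->SOD": 0.30,
    "gamma:HIF1->p53": 0.08,
    "S:HIF1->p53": 0.70,
    "n:HIF1->p53": 4,
    "gamma:p53->HIF1": 0.85,
    "gamma:HIF1->HIF1": 1.50,
    "D:HIF1": 0.25,
    "A:HIF1": 0.32,
    "gamma:ATP->mTOR": 2.5,
    "S:ATP->mTOR": 2.2,
    "n:ATP->mTOR": 6,
    "gamma:mTOR->HIF1": 6.0,
    "S:mTOR->HIF1": 0.66,
    "n:mTOR->HIF1": 8,
    "gamma:SOD->p53": 5.0,
}

# --- nodes -----------------------------------------------------------------
# (id, name, role, clamped, default_initial)

_GENES = [
    ("RAS", "RAS", 0.50),
    ("PI3K", "PI3K", 0.45),
    ("Akt", "Akt", 0.35),
    ("PTEN", "PTEN", 0.35),
    ("mTOR", "mTOR", 0.35),
    ("AMPK", "AMPK", 0.50),
    ("cMyc", "c-Myc", 0.45),
    ("HIF1", "HIF-1", 0.30),
    ("p53", "p53", 0.30),
    ("PDK", "PDK", 0.35),
    ("VEGF", "VEGF", 0.40),
    ("SOD", "SOD", 0.40),
    ("NOX", "NOX", 0.35),
]

_ENZYMES = [
    ("GluT1", "glucose transporter GLUT1", 0.40),
    ("HK2", "hexokinase 2", 0.40),
    ("GPI", "glucose-6-phosphate isomerase", 0.45),
    ("PFKFB3", "PFK-2/FBPase (F2,6BP synthesis)", 0.35),
    ("PFK1", "phosphofructokinase 1", 0.40),
    ("ALDO", "aldolase", 0.45),
    ("GAPDH", "glyceraldehyde-3-P dehydrogenase", 0.45),
    ("PGK1", "phosphoglycerate kinase", 0.45),
    ("ENO1", "enolase", 0.45),
    ("PKM2", "pyruvate kinase M2", 0.40),
    ("LDH", "lactate dehydrogenase", 0.35),
    ("MCT4", "lactate exporter MCT4", 0.40),
    ("PDH", "pyruvate dehydrogenase (to citrate)", 0.35),
    ("TCA", "TCA-cycle dehydrogenases (lumped)", 0.40),
    ("ETC", "electron transport / ATP synthase", 0.40),
    ("G6PD", "pentose-phosphate entry (to R5P)", 0.40),
    ("PHGDH", "serine synthesis (from 3PG)", 0.40),
]

# (id, name, clamped, default_initial)
_METABOLITES = [
    ("Glc_ex", "extracellular glucose", True, 1.00),
    ("Glc", "intracellular glucose", False, 0.50),
    ("G6P", "glucose-6-phosphate", False, 0.50),
    ("F6P", "fructose-6-phosphate", False, 0.50),
    ("F26BP", "fructose-2,6-bisphosphate", False, 0.30),
    ("FBP", "fructose-1,6-bisphosphate", False, 0.50),
    ("GAP", "glyceraldehyde-3-phosphate", False, 0.50),
    ("BPG", "1,3-bisphosphoglycerate", False, 0.30),
    ("PG3", "3-phosphoglycerate", False, 0.50),
    ("PEP", "phosphoenolpyruvate", False, 0.40),
    ("Pyr", "pyruvate", False, 0.50),
    ("Lac", "lactate", False, 0.50),
    ("Lac_ex", "extracellular lactate", True, 0.10),
    ("Cit", "citrate", False, 0.40),
    ("R5P", "ribose-5-phosphate", False, 0.20),
    ("Ser", "serine", False, 0.20),
    ("ROS", "reactive oxygen species", False, 0.20),
    ("H2O2", "hydrogen peroxide", False, 0.10),
    ("ATP", "ATP", False, 1.00),
    ("ADP", "ADP", False, 1.00),
    ("NADH", "NADH", False, 1.00),
    ("NAD", "NAD+", False, 1.00),
    ("O2", "oxygen", True, 0.05),
]

# --- gene/enzyme production-degradation kinetics ---------------------------
# node id -> (A basal production, D degradation)

_GENE_KINETICS = {
    "RAS": (0.50, 1.0),
    "PI3K": (0.30, 1.0),
    "Akt": (0.32, 1.0),
    "PTEN": (0.30, 1.0),
    "mTOR": (0.25, 1.0),
    "AMPK": (0.55, 1.0),
    "cMyc": (0.35, 1.0),
    "HIF1": (0.27, 0.6),  # slow: sets the oscillation timescale
    "p53": (0.12, 1.0),
    "PDK": (0.30, 1.0),
    "VEGF": (0.28, 1.0),
    "SOD": (0.30, 1.0),
    "NOX": (0.30, 1.0),
    # enzymes
    "GluT1": (0.30, 1.0),
    "HK2": (0.28, 1.0),
    "GPI": (0.35, 1.0),
    "PFKFB3": (0.28, 1.0),
    "PFK1": (0.32, 1.0),
    "ALDO": (0.45, 1.0),
    "GAPDH": (0.38, 1.0),
    "PGK1": (0.45, 1.0),
    "ENO1": (0.45, 1.0),
    "PKM2": (0.30, 1.0),
    "LDH": (0.25, 1.0),
    "MCT4": (0.30, 1.0),
    "PDH": (0.30, 1.0),
    "TCA": (0.30, 1.0),
    "ETC": (0.30, 1.0),
    "G6PD": (0.35, 1.0),
    "PHGDH": (0.35, 1.0),
}

# --- regulation edges ------------------------------------------------------
# (source, target, gamma, S, n); gamma > 1 activation, < 1 inhibition.

_EDGES_GENE_GENE = [
    ("RAS", "PI3K", 1.60, 0.50, 4),
    ("VEGF", "PI3K", 1.30, 1.00, 4),
    ("Akt", "PI3K", 2.60, 0.75, 4),
    ("PTEN", "PI3K", 0.60, 0.80, 4),
    ("PI3K", "Akt", 2.80, 0.70, 4),
    ("PTEN", "Akt", 0.85, 1.00, 4),
    ("PDK", "Akt", 1.20, 1.00, 4),
    ("Akt", "mTOR", 2.50, 0.70, 4),
    ("AMPK", "mTOR", 0.50, 0.80, 4),
    ("Akt", "cMyc", 2.00, 0.70, 4),
    ("p53", "cMyc", 0.70, 1.00, 4),
    ("mTOR", "HIF1", 2.50, 0.80, 4),
    ("cMyc", "HIF1", 1.30, 0.90, 4),
    ("HIF1", "HIF1", 8.00, 0.50, 6),
    ("p53", "HIF1", 0.50, 0.80, 1),
    ("Akt", "HIF1", 1.30, 0.80, 4),
    ("HIF1", "p53", 0.50, 0.80, 1),
    ("p53", "p53", 8.00, 0.50, 6),
    ("SOD", "p53", 2.50, 0.80, 4),
    ("Akt", "p53", 0.85, 1.00, 4),
    ("AMPK", "p53", 1.30, 0.80, 4),
    ("p53", "PTEN", 2.00, 1.10, 4),
    ("PTEN", "p53", 1.30, 0.80, 4),
    ("HIF1", "VEGF", 2.50, 1.00, 4),
    ("RAS", "VEGF", 1.50, 0.50, 4),
    ("VEGF", "SOD", 2.00, 0.80, 4),  # the oscillation / bistability dial
    ("p53", "SOD", 1.40, 1.00, 4),
    ("HIF1", "NOX", 2.50, 1.00, 4),
    ("AMPK", "NOX", 0.60, 0.80, 4),
    ("HIF1", "PDK", 4.00, 1.20, 4),
    ("p53", "PDK", 0.40, 0.90, 4),
    ("HIF1", "AMPK", 0.60, 1.20, 4),
]

_EDGES_GENE_ENZYME = [
    ("HIF1", "GluT1", 3.00, 1.00, 4),
    ("cMyc", "GluT1", 1.50, 0.90, 4),
    ("p53", "GluT1", 0.60, 1.00, 4),
    ("HIF1", "HK2", 2.50, 1.00, 4),
    ("cMyc", "HK2", 1.40, 0.90, 4),
    ("Akt", "HK2", 1.50, 0.80, 4),
    ("HIF1", "GPI", 2.50, 1.00, 4),
    ("HIF1", "PFKFB3", 2.00, 1.00, 4),
    ("AMPK", "PFKFB3", 1.50, 0.80, 4),
    ("Akt", "PFK1", 1.80, 0.80, 4),
    ("mTOR", "GAPDH", 1.60, 0.90, 4),
    ("HIF1", "PKM2", 2.50, 1.00, 4),
    ("cMyc", "PKM2", 1.50, 0.90, 4),
    ("HIF1", "LDH", 6.00, 0.90, 6),
    ("cMyc", "LDH", 1.30, 0.90, 4),
    ("p53", "LDH", 0.80, 1.00, 4),
    ("HIF1", "MCT4", 3.00, 1.00, 4),
    ("PDK", "PDH", 0.30, 0.80, 4),
    ("p53", "PDH", 6.00, 0.90, 6),
    ("p53", "TCA", 2.00, 0.90, 4),
    ("cMyc", "TCA", 1.40, 0.90, 4),
    ("p53", "ETC", 2.50, 0.90, 4),
    ("HIF1", "ETC", 0.50, 1.00, 4),
    ("p53", "G6PD", 0.60, 0.90, 4),
    ("cMyc", "PHGDH", 1.50, 0.90, 4),
]

_EDGES_METABOLITE_GENE = [
    ("O2", "HIF1", 0.25, 0.010, 4),  # hypoxia switch: inhibition lifts below ~0.01
    ("ROS", "HIF1", 1.40, 0.60, 4),
    ("Lac", "HIF1", 1.20, 1.00, 4),
    ("ROS", "p53", 1.30, 0.60, 4),
    ("H2O2", "p53", 1.20, 0.50, 4),
    ("ATP", "AMPK", 0.50, 1.20, 4),
    ("ATP", "mTOR", 1.80, 1.20, 4),
    ("Glc", "mTOR", 1.30, 0.50, 4),
    ("Lac", "VEGF", 1.30, 1.00, 4),
    ("ROS", "PTEN", 0.80, 0.80, 4),
]

_EDGES_METABOLITE_ENZYME = [
    ("F26BP", "PFK1", 1.80, 0.50, 4),
    ("ATP", "PFK1", 0.70, 1.20, 4),
    ("Cit", "PFK1", 0.70, 0.80, 4),
    ("G6P", "HK2", 0.70, 1.00, 4),
    ("NADH", "PDH", 0.80, 1.20, 4),
    ("R5P", "G6PD", 0.80, 0.80, 4),
]

# --- reactions -------------------------------------------------------------
# (id, substrates, products, enzyme, rate_law, params)

_REACTIONS = [
    ("R_GLUT", [("Glc_ex", 1)], [("Glc", 1)], "GluT1", "michaelis_menten",
     {"vmax": 0.6, "km": 1.0}),
    ("R_HK", [("Glc", 1), ("ATP", 1)], [("G6P", 1), ("ADP", 1)], "HK2",
     "michaelis_menten", {"vmax": 1.2, "km_Glc": 0.5, "km_ATP": 0.5}),
    ("R_GPI", [("G6P", 1)], [("F6P", 1)], "GPI", "michaelis_menten",
     {"vmax": 1.2, "km": 0.5}),
    ("R_PFKFB", [("F6P", 1), ("ATP", 1)], [("F26BP", 1), ("ADP", 1)], "PFKFB3",
     "michaelis_menten", {"vmax": 0.3, "km_F6P": 0.5, "km_ATP": 0.5}),
    ("R_F26BP_USE", [("F26BP", 1)], [("F6P", 1)], None, "mass_action", {"k": 0.3}),
    ("R_PFK", [("F6P", 1), ("ATP", 1)], [("FBP", 1), ("ADP", 1)], "PFK1",
     "michaelis_menten", {"vmax": 1.2, "km_F6P": 0.5, "km_ATP": 0.5}),
    ("R_ALDO", [("FBP", 1)], [("GAP", 2)], "ALDO", "michaelis_menten",
     {"vmax": 1.2, "km": 0.5}),
    ("R_GAPDH", [("GAP", 1), ("NAD", 1)], [("BPG", 1), ("NADH", 1)], "GAPDH",
     "michaelis_menten", {"vmax": 3.0, "km_GAP": 0.5, "km_NAD": 0.3}),
    ("R_PGK", [("BPG", 1), ("ADP", 1)], [("PG3", 1), ("ATP", 1)], "PGK1",
     "michaelis_menten", {"vmax": 4.0, "km_BPG": 0.3, "km_ADP": 0.5}),
    ("R_ENO", [("PG3", 1)], [("PEP", 1)], "ENO1", "michaelis_menten",
     {"vmax": 4.0, "km": 0.4}),
    ("R_PK", [("PEP", 1), ("ADP", 1)], [("Pyr", 1), ("ATP", 1)], "PKM2",
     "michaelis_menten", {"vmax": 4.0, "km_PEP": 0.4, "km_ADP": 0.5}),
    ("R_LDH", [("Pyr", 1), ("NADH", 1)], [("Lac", 1), ("NAD", 1)], "LDH",
     "michaelis_menten", {"vmax": 2.5, "km_Pyr": 0.5, "km_NADH": 0.3}),
    ("R_MCT", [("Lac", 1)], [("Lac_ex", 1)], "MCT4", "michaelis_menten",
     {"vmax": 1.0, "km": 0.5}),
    ("R_PDH", [("Pyr", 1), ("NAD", 1)], [("Cit", 1), ("NADH", 1)], "PDH",
     "michaelis_menten", {"vmax": 1.5, "km_Pyr": 0.5, "km_NAD": 0.3}),
    ("R_TCA", [("Cit", 1), ("NAD", 3)], [("NADH", 3)], "TCA", "michaelis_menten",
     {"vmax": 1.2, "km_Cit": 0.5, "km_NAD": 0.3}),
    ("R_ETC", [("NADH", 1), ("ADP", 3), ("O2", 1)], [("NAD", 1), ("ATP", 3)], "ETC",
     "michaelis_menten", {"vmax": 4.0, "km_NADH": 0.3, "km_ADP": 0.5, "km_O2": 0.01}),
    ("R_G6PD", [("G6P", 1)], [("R5P", 1)], "G6PD", "michaelis_menten",
     {"vmax": 0.3, "km": 0.5}),
    ("R_PHGDH", [("PG3", 1)], [("Ser", 1)], "PHGDH", "michaelis_menten",
     {"vmax": 0.3, "km": 0.5}),
    ("R_NOX", [("O2", 1)], [("ROS", 1)], "NOX", "michaelis_menten",
     {"vmax": 0.4, "km": 0.02}),
    ("R_SOD", [("ROS", 1)], [("H2O2", 1)], "SOD", "michaelis_menten",
     {"vmax": 1.0, "km": 0.5}),
    ("R_CAT", [("H2O2", 1)], [], None, "mass_action", {"k": 1.0}),
    ("R_ATPASE", [("ATP", 1)], [("ADP", 1)], None, "mass_action", {"k": 0.6}),
    ("R_R5P_USE", [("R5P", 1)], [], None, "mass_action", {"k": 0.5}),
    # slow turnover pins the adenine and NAD pools (conserved otherwise)
    ("R_ADN_SYN", [], [("ADP", 1)], None, "mass_action", {"k": 0.06}),
    ("R_ADN_DEG", [("ADP", 1)], [], None, "mass_action", {"k": 0.04}),
    ("R_NAD_SYN", [], [("NAD", 1)], None, "mass_action", {"k": 0.06}),
    ("R_NAD_DEG", [("NAD", 1)], [], None, "mass_action", {"k": 0.04}),
    ("R_SER_USE", [("Ser", 1)], [], None, "mass_action", {"k": 0.5}),
]

#: The comprehensive glycolysis chain used for stoichiometric path sums:
#: one extracellular glucose in, two pyruvate and net two ATP out.
GLYCOLYSIS_CHAIN = [
    "R_GLUT", "R_HK", "R_GPI", "R_PFK", "R_ALDO", "R_GAPDH", "R_PGK", "R_ENO", "R_PK",
]

REFERENCE_CHAINS = {
    "glycolysis": {
        "reactions": GLYCOLYSIS_CHAIN,
        "start": "Glc_ex",
        "targets": ["Pyr", "ATP"],
    }
}


def reference_tables() -> tuple:
    """The four declarative model tables (nodes, edges, reactions, kinetics)."""
    node_rows = []
    for nid, name, init in _GENES:
        node_rows.append({"id": nid, "name": name, "role": "gene", "clamped": 0,
                          "default_initial": init})
    for nid, name, init in _ENZYMES:
        node_rows.append({"id": nid, "name": name, "role": "enzyme", "clamped": 0,
                          "default_initial": init})
    for nid, name, clamped, init in _METABOLITES:
        node_rows.append({"id": nid, "name": name, "role": "metabolite",
                          "clamped": int(clamped), "default_initial": init})
    edge_rows = [
        {"source": s, "target": t, "gamma": g, "S": S, "n": n}
        for s, t, g, S, n in (_EDGES_GENE_GENE + _EDGES_GENE_ENZYME
                              + _EDGES_METABOLITE_GENE + _EDGES_METABOLITE_ENZYME)
    ]
    rxn_rows = [
        {
            "id": rid,
            "substrates": ";".join(f"{n}:{c}" for n, c in subs),
            "products": ";".join(f"{n}:{c}" for n, c in prods),
            "enzyme": enz or "",
            "rate_law": law,
        }
        for rid, subs, prods, enz, law, _params in _REACTIONS
    ]
    kin_rows = []
    for nid, (A, D) in _GENE_KINETICS.items():
        kin_rows.append({"kind": "gene", "target": nid, "param": "A", "value": A})
        kin_rows.append({"kind": "gene", "target": nid, "param": "D", "value": D})
    for rid, _s, _p, _e, _law, params in _REACTIONS:
        for k, v in params.items():
            kin_rows.append({"kind": "reaction", "target": rid, "param": k, "value": v})
    return (
        pd.DataFrame(node_rows),
        pd.DataFrame(edge_rows),
        pd.DataFrame(rxn_rows),
        pd.DataFrame(kin_rows),
    )


def reference_init_ranges() -> dict:
    """Seeded initial-condition ranges for attractor searches.

    Genes and enzymes are sampled over (0, 1.6); metabolites over
    (0, 2.5 x default) so pools start near their physiological scale.
    """
    ranges = {}
    for nid, _name, _init in _GENES:
        ranges[nid] = (0.0, 1.6)
    for nid, _name, _init in _ENZYMES:
        ranges[nid] = (0.0, 1.6)
    for nid, _name, clamped, init in _METABOLITES:
        if not clamped:
            ranges[nid] = (0.0, 2.5 * init)
    return ranges


#: Diffusion coefficient used for the reference landscape ensembles: small
#: enough that all four basins stay resolved over the sampling horizon,
#: large enough to populate the projection.  The nonequilibrium scans use
#: SCAN_NOISE, slightly larger so inter-basin probability currents are
#: resolvable at modest ensemble sizes.
REFERENCE_NOISE = 0.002
SCAN_NOISE = 0.004


def reference_sim_config(seed: int = 0, **overrides):
    """A :class:`~fluxscape.simulate.SimulationConfig` tuned for this model."""
    from .simulate import SimulationConfig

    kw = dict(
        step=0.025, horizon=200.0, noise=REFERENCE_NOISE, seed=seed,
        n_starts=60, attractor_tol=0.08, transient_frac=0.3, sample_every=10,
        init_ranges=reference_init_ranges(),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def build_reference_model(gamma_vegf_sod: float | None = None,
                          o2: float | None = None,
                          variant: str = "baseline") -> NetworkModel:
    """Assemble the reference model, optionally overriding the two scan dials.

    ``variant="baseline"`` is the quadristable configuration (N/I/P/G);
    ``variant="oscillatory"`` applies :data:`OSCILLATORY_OVERRIDES`, the
    relaxation-oscillator calibration in which the VEGF->SOD fold change
    controls oscillation onset.  ``gamma_vegf_sod`` overrides the
    VEGF->SOD fold change; ``o2`` the clamped oxygen level (baseline
    0.05; the normal-glycolysis switch sits near 0.01).
    """
    model = assemble_model(*reference_tables())
    if variant == "oscillatory":
        for path, value in OSCILLATORY_OVERRIDES.items():
            model = set_parameter(model, path, value)
    elif variant != "baseline":
        raise ValueError(f"unknown variant {variant!r}")
    if gamma_vegf_sod is not None:
        model = set_parameter(model, "gamma:VEGF->SOD", gamma_vegf_sod)
    if o2 is not None:
        model = set_parameter(model, "clamp:O2", o2)
    return model
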