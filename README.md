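# fluxscape

Nonequilibrium landscape–flux analysis of coupled gene-regulatory/metabolic
networks, built around the question of how cancer cells settle into, and
switch between, glycolytic and oxidative (OXPHOS) metabolic programs.

The package models a cell as a stochastic dynamical system. Gene and enzyme
levels follow production–degradation kinetics with multiplicative
shifted-Hill regulation,

    dX_i/dt = A_i * prod_j H_ji(X_j) - D_i X_i,
    H_ji(x) = S^n/(S^n + x^n) + gamma * x^n/(S^n + x^n),

and metabolite concentrations follow stoichiometry-signed sums of
enzyme-scaled reaction velocities (Michaelis–Menten and mass-action rate
laws). Additive noise of diffusion coefficient D turns the deterministic
attractors into a steady-state probability distribution P_ss, from which the
package computes:

* the **potential landscape** U = −ln P_ss projected onto the (LDH, PDH)
  plane, with watershed basins, minimax saddles and barrier heights;
* the **steady-state probability flux** J = μρ − D∇ρ, its mean magnitude and
  the **entropy production rate** EPR = Σ |J|²/(Dρ) — the rotational driving
  force and thermodynamic cost that vanish only in detailed balance;
* **dominant transition paths** between attractors by minimizing a
  discretized Freidlin–Wentzell action Σ (|Δx||F| − Δx·F)/(2D);
* **bifurcation scans**, limit-cycle detection, and oscillation metrics
  (flux loop integral, rotation coherence, G↔P switching times);
* barrier-based **global sensitivity analysis** (each interaction strength
  +1%, common random numbers) and **therapeutic-target screening** via the
  constant-force deformation F'(x_i) = F(x_i) + c_i;
* **metabolic-state clustering** of expression matrices: per-gene normalized
  glycolysis/OXPHOS group scores plus K-means with canonical state labels.

A shipped 53-node reference configuration (13 genes, 17 enzymes, 23
metabolites, 73 regulatory interactions) couples PI3K/Akt/mTOR signalling,
the HIF-1/p53 antagonism, AMPK energy sensing and the VEGF–SOD–ROS axis to
glycolysis and the TCA cycle. Its parameter values are synthetic,
calibrated so that the baseline is quadristable — normal (N), intermediate
(I), OXPHOS (P) and glycolysis (G) states with the expected (LDH, PDH)
signature — and so that a documented oscillatory variant develops a
clockwise N→P→G limit cycle under strong VEGF→SOD regulation. Every emitted
table carries that watermark. A `synthetic_data` module generates the toy
dynamical systems (with closed-form truths) and four-state expression
matrices used throughout the test suite.

## Worked example

Enumerate the metabolic attractors of the reference network and measure its
landscape barriers:

```bash
$ fluxscape attractors --model reference --seed 1 --out attractors.tsv
$ fluxscape landscape --model reference --seed 1 --out barriers.tsv
```

The attractor table (selected columns) shows the four states and their
basin weights:

```
label  basin_weight  LDH   PDH
I      0.57          0.73  0.54
G      0.18          1.24  0.23
P      0.18          0.23  1.22
N      0.07          0.25  0.30
```

The glycolysis state sits at high LDH/low PDH, the OXPHOS state at the
mirrored corner, the intermediate between them, and the normal state at
both-low. The landscape command reports each basin minimum and the barrier
(in units of U = −ln P_ss) from every saddle to its adjacent basins; the
intermediate state's shallow escape barrier is what makes it the hub through
which the other states interconvert. In Python the same pipeline is:

```python
from fluxscape import build_reference_model, reference_sim_config
from fluxscape.simulate import find_attractors, langevin_ensemble, as_dynamics
from fluxscape.landscape import landscape_from_samples

model = build_reference_model()
cfg = reference_sim_config(seed=1)
attractors = find_attractors(model, cfg, projection=("LDH", "PDH"))
samples = langevin_ensemble(model, cfg, n_walkers=350)
grid, minima, saddles, labels, barriers = landscape_from_samples(
    samples, ("LDH", "PDH"), names=list(as_dynamics(model).names), bins=70)
```

Other entry points: `fluxscape scan` (bifurcation diagrams, e.g.
`--parameter clamp:O2`), `fluxscape epr-scan` (flux/EPR along a dial),
`fluxscape oscillation` (period, coherence, switching times of the
oscillatory variant, `--model reference:oscillatory`), `fluxscape paths`,
`fluxscape sensitivity`, `fluxscape therapy`, `fluxscape cluster` and
`fluxscape synth`.

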