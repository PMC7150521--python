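# Methods

## The model

`fluxscape` analyses a coupled gene-regulatory/metabolic dynamical system.
Gene and enzyme nodes $X_i$ follow production–degradation kinetics with
multiplicative regulation,

$$\dot X_i = A_i \prod_j H_{ji}(X_j) - D_i X_i,
\qquad
H_{ji}(x) = \frac{S_{ji}^n}{S_{ji}^n + x^n} + \gamma_{ji}\,\frac{x^n}{S_{ji}^n + x^n},$$

where the *shifted Hill factor* $H$ runs monotonically from 1 (no regulator)
to the fold-change $\gamma$ (saturating regulator); $\gamma > 1$ is
activation, $\gamma < 1$ inhibition, $S$ the half-threshold and $n$ the Hill
coefficient. Metabolite nodes $Y_i$ follow stoichiometry-signed sums of
enzyme-scaled reaction velocities,

$$\dot Y_i = \sum_j X_{e(j)}\, r_j(Y),$$

with rate laws drawn from a registry (mass action, irreversible
Michaelis–Menten with one or several substrates, and Michaelis–Menten with
saturating activator/inhibitor factors). Boundary species — extracellular
glucose and lactate, oxygen — are *clamped* nodes: their drift is identically
zero and their levels serve as scan parameters. All levels are in arbitrary
units; thresholds and tolerances are expressed relative to node scales
(typical levels are order 0.1–2).

Stochasticity is additive: $dx = F(x)\,dt + \sqrt{2D}\,dW$ with diffusion
coefficient $D$, integrated by Euler–Maruyama with nonnegativity enforced by
clipping at zero (concentrations cannot go negative; the clip is a boundary
condition, not part of the drift). The landscape is
$U = -\ln P_{ss}$ on a 2D projection — by convention the (LDH, PDH) plane,
lactate dehydrogenase marking the glycolytic branch and pyruvate
dehydrogenase the mitochondrial branch.

## The reference configuration

The shipped 53-node network (13 genes, 17 enzymes, 23 metabolites, 73
regulatory edges of which 32 are gene–gene) couples PI3K/Akt/mTOR growth
signalling, the HIF-1/p53 antagonism, AMPK energy sensing and the
VEGF–SOD–ROS axis to glycolysis, the TCA cycle/oxidative phosphorylation and
their branch pathways (pentose phosphate, serine synthesis, lactate export).
Sequential reactions are lumped (pyruvate → citrate stands for the pyruvate
dehydrogenase complex plus citrate synthase), so one extracellular glucose
yields two pyruvate and a net two ATP through the glycolytic chain — a
structural invariant checked by `validate_model`.

**All numeric parameter values are synthetic.** The interaction strengths
were calibrated in-house and are watermarked as such in every emitted table;
they are not transcribed from any publication. The calibration targets were
qualitative:

* **Quadristability.** At baseline the HIF-1/p53 pair forms a double-positive
  self-activation circuit (Hill $n=6$, fold-change 8) with gentle Michaelian
  mutual inhibition. This yields exactly four attractors with the expected
  (LDH, PDH) signature: normal **N** (both low), glycolysis **G** (LDH high),
  OXPHOS **P** (PDH high) and an intermediate **I** (both mid). The gentle
  (n = 1) inhibition is what stabilizes the co-expressed central state; steep
  mutual inhibition destroys it.
* **Hypoxia switch.** Oxygen inhibits HIF-1 with half-threshold
  $S = 0.01$; at the normal clamped level $[O_2] = 0.05$ the inhibition is
  engaged, and lowering oxygen through $\approx 0.01$ releases HIF-1, which
  switches the normal state to a normal-glycolysis phenotype. The located
  transition ($\approx 0.0105$) follows the designed threshold.
* **Oscillatory regime.** The `variant="oscillatory"` configuration applies a
  documented override set: HIF-1 becomes a slow integrator (degradation
  0.25), its self-activation is weakened, the ATP→mTOR→HIF-1 energy-sensing
  arm is strengthened and sharpened, HIF-1⊣p53 is made strong, and the
  VEGF→SOD→p53 drive is put under the control of the VEGF→SOD fold-change.
  Above onset (fold-change ≈ 3.5–4) the network develops a relaxation limit
  cycle that visits the N, P and G neighbourhoods clockwise in the (LDH, PDH)
  plane. The glycolysis→OXPHOS leg passes through the normal corner and is
  governed by the slow HIF-1 decay, so it takes several times longer than the
  OXPHOS→glycolysis return — the switching-time asymmetry the acceptance
  suite checks. A separate oscillatory calibration is needed because the
  baseline quadristable parameter set does not oscillate under the SOD dial
  alone; the variant is the package's own account of the oscillatory
  mechanism (energy-driven slow positive arm plus fast antagonist), not a
  transcription of external values.

Conserved metabolite pools (ATP+ADP, NAD+NADH) are pinned by slow synthesis/
degradation reactions; strictly conserved pools would form a continuum of
steady states and interact badly with nonnegativity clipping.

## Landscape, flux and thermodynamics

$P_{ss}$ is estimated by histogramming post-transient Langevin samples of
the two projection coordinates over a walker ensemble — a true marginal over
the remaining 51 dimensions, never a re-simulated 2D system. Defaults: 70–100
bins over the sample range (5% padding), mild Gaussian smoothing of one bin
for extremum detection only, empty bins masked and capped at
$\max U + 1$. Basins are found by flooding cells in ascending potential with
union-find (4-connectivity); the first contact between two catchments is
exactly their minimax saddle (verified against exhaustive path enumeration).
Basins are discarded when their prominence falls below a configured threshold (0.3–0.5 depending on the analysis) or their peak
mass is below three samples (histogram-noise minima).

Two sampling regimes are used deliberately:

* **Barriers/basins:** $D = 0.002$. All four basins are metastable over the
  200-time-unit horizon and seed-robust. The price is that the rarely visited
  G–P and G–N corridors sit near the single-sample floor, so barrier
  *changes* are quantitatively meaningful mainly at the well-resolved G–I
  saddle; standard errors from walker-block splits make this visible.
* **Flux/EPR scans:** $D = 0.004$ with a 60% burn-in. Larger noise resolves
  the inter-basin probability currents at modest ensemble sizes.

The projected steady-state flux is reconstructed from the projected
Fokker–Planck current $J = \mu \rho - D \nabla \rho$, with $\mu$ the per-bin
conditional mean drift of the projected coordinates and $\rho$ the stationary
density; the entropy production rate is
$\mathrm{EPR} = \int \lVert J\rVert^2 / (D\rho)$. Both estimators are
validated against closed forms: detailed-balance systems give flux and EPR
statistically indistinguishable from zero, and the linear rotational system
$\dot x = -x + \omega y,\ \dot y = -y - \omega x$ reproduces
$J = \omega(y, -x)\rho$ and $\mathrm{EPR} = 2\omega^2$. Oscillation
*coherence* has no standard definition, so it is defined operationally
here: trajectories are cut into windows, each window votes
by the sign of its net angular displacement about the centroid, and the
majority fraction is rescaled to [0, 1] so that pure diffusion scores ≈ 0 and
deterministic rotation scores 1. Switching times are mean first-passage
durations between entries into configurable balls around the G and P
signatures.

## Transition paths

Dominant paths minimize the Freidlin–Wentzell action
$S = \int \lVert\dot x - F(x)\rVert^2/(4D)\,dt$ over waypoint chains in the
full state space (projection happens only at reporting time). The
per-segment time step is eliminated analytically — the optimal segment moves
at the local drift speed — leaving the geometric form
$S = \sum_k (\lVert\Delta x_k\rVert\,\lVert F_k\rVert - \Delta x_k\!\cdot\!F_k)/(2D)$,
minimized by L-BFGS with an analytic gradient (model Jacobians by batched
finite differences). An equal-arclength penalty (vanishing at the optimum)
prevents the discretization from tunnelling long segments through zeros of
the drift. Nonnegativity bounds apply only to models on the nonnegative
orthant. The 1D double-well action agrees with an independent quadrature
oracle $\int |F|\,dx / D$ to better than 2%.

## Sensitivity and therapy screening

Global sensitivity scales one interaction parameter at a time by +1%
(configurable) and re-estimates the landscape **with the same random seed**
as the baseline: with common random numbers most Monte-Carlo error cancels
in the barrier differences (a zero perturbation gives exactly zero change).
Perturbations that change the basin count are reported categorically, not
numerically. Therapy screening deforms a gene/enzyme drift by a constant,
$F'(x_i) = F(x_i) + c_i$ with $|c| = 2\times10^{-4}$ by default (positive =
activation), and scores interventions by the signed change of the cancer
basins' escape barriers — negative changes destabilize the state, a positive
therapeutic effect. Oscillation therapy scores the change of the
center-island barrier of the ring landscape (max $U$ inside the cycle
polygon minus min $U$ on the cycle), validated on a radial-well toy with a
closed-form island height.

## Expression clustering

Samples are scored by per-gene z-scores across samples (zero-variance genes
contribute 0; min–max normalization available behind a flag) averaged within
a glycolysis gene group and a TCA/OXPHOS gene group; K-means with $k=4$ and
seeded restarts partitions the score plane. Cluster ids are canonicalized by
centroid geometry (1 normal-like, 2 glycolysis, 3 OXPHOS, 4 intermediate) so
labels are comparable across runs.

## Synthetic data: what it emulates, what it does not

The expression generator draws four latent states with group-mean structure
(normal low/low, glycolysis high/low, OXPHOS low/high, intermediate
mid/mid), 60 samples per state, 20 genes per group, per-gene offsets and
Gaussian noise (sd 1.2, chosen so the clouds overlap but remain
recoverable). It emulates the score-plane geometry of real tumour cohorts;
it does not emulate count noise, library-size effects, batch structure,
correlated gene modules, or unbalanced state prevalence, so clustering
recovery here bounds only the algorithmic pipeline, not performance on real
RNA-seq. The toy dynamical systems (double wells, linear rotational system,
van-der-Pol-type oscillator, mutual-inhibition switch, bounded fold normal
form, Ornstein–Uhlenbeck) each declare machine-checkable truths and are the
oracle backbone of the test suite.

## Numerical choices and problem sizes

Deterministic trajectories use LSODA (rtol $10^{-7}$) or fixed-step RK4 for
long scans; attractor search integrates 48–80 seeded starts (uniform over
per-node ranges; metabolites over 2.5× their default scale) and merges
endpoints by single-linkage with radius 0.08 in a per-node rescaled metric,
verifying $\lVert F\rVert$ at each representative and reporting
non-convergent starts. Limit-cycle detection requires a post-transient
amplitude above 10× the merge radius plus recurrent Poincaré crossings;
amplitudes within a factor two of threshold flag the result. Bifurcation
scans refine transitions by bisection to 1–5% of the scan range. Landscape
ensembles default to 300–400 walkers × 200 time units (about 2–3 × 10⁵
samples); the test and acceptance runs use these desk-scale sizes, which
keep every stage in seconds-to-minutes on one CPU while leaving all
qualitative results seed-stable.

## Known limitations

* Basin weights reflect the initial-condition distribution when barriers are
  large relative to the noise (true steady-state weights would need many
  barrier crossings or an alternative $P_{ss}$ estimator, which is out of
  scope).
* Flux, EPR and barriers are 2D-projection quantities; full-dimensional
  thermodynamics is not attempted.
* The high saddles of the quadristable landscape at $D = 0.002$ sit near the
  histogram sampling floor; their absolute heights are lower bounds and the
  screening analyses lean on the well-sampled saddles.
* The oscillatory regime is a separate calibration of the same network
  rather than a continuation of the baseline parameter set.
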