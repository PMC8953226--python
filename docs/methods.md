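# Methods

This note documents the models, numerical choices and limitations behind
`sretools`. It is written for users who want to know what the numbers mean,
not how the code is organised.

## The experiment being modelled

A glucose-limited aerobic chemostat (working volume 1.7 L, feed 22.5 g/L
glucose, dilution rate D = 0.1 h⁻¹) is perturbed by switching the feed pump
off for 2 minutes, first once (the *non-adapted* response) and then
repeatedly in 2-min-off / 7-min-on cycles (a 9-min limitation → starvation →
limitation cycle). During the cyclic phase the feed-on rate is raised to
3.64 mL·min⁻¹ so the cycle-averaged dilution rate stays at 0.1 h⁻¹. After
five residence times of cycling the culture reaches a *dynamic steady state*
(DS) that is compared with the *reference steady state* (RS). Observables
are extracellular glucose, biomass dry matter, off-gas O₂/CO₂ fractions
logged once per minute, and absolutely quantified intracellular metabolite
panels (µmol per g dry biomass, biological triplicates).

## Chemostat model (`sretools.reactor`)

Glucose and biomass follow the standard stirred-tank balances

    dC/dt = F(t)/V · (C_feed − C) − q_s(C)·X,   q_s = q_max·C/(K_M + C)
    dX/dt = (µ − F(t)/V)·X,                      µ = Y_xs·(q_s − q_m)·M_glc

with the harvest pump tracking the feed pump, so the volume is constant and
there is no washout while the feed is off. Integration is fixed-step
classical Runge–Kutta (RK4); feed-switch events must land on grid nodes
(enforced, not interpolated), glucose is clipped at zero after each step,
and a `frozen_biomass` toggle supports analytic checks (ΔX over one 9-min
cycle at D = 0.1 h⁻¹ is < 0.3%). The system is non-stiff at these
parameters; at dt = 1 s the long-run steady state agrees with the
closed-form Monod solution C* = K_M·q_req/(q_max − q_req),
q_req = D/(Y_xs·M_glc), to well under 0.5%.

Kinetic defaults are `q_max = 11.2 mmol·g⁻¹·h⁻¹`, `K_M = 1000 µmol·L⁻¹`,
`Y_xs = 0.494 g/g`. They are chosen so that the continuous steady state sits
near 10% of K_M (≈ 111 µmol/L), the relation reported for the high-affinity
hexose transporters at this growth rate. All kinetic values are config
inputs; nothing downstream assumes these defaults.

Metabolic regimes are classified from glucose alone: overflow strictly above
207 µmol/L, starvation strictly below 53 µmol/L, limitation otherwise (both
boundaries inclusive to limitation, matching the ">207"/"below 53"
convention). Residence fractions attribute each inter-sample interval to its
left endpoint's regime — no interpolation across crossings — and sum to 1 to
machine precision. The semilog depletion slope is a least-squares fit of
ln C vs t, sign-negated so depletion is positive; it is reported both per
second and per minute because the normalisation of published depletion
slopes is ambiguous, and this package deliberately does not endorse either
reading.

## Off-gas sensor model (`sretools.offgas`)

Tubing and foam traps between reactor and analysers act as mixing chambers;
each channel is modelled as one lumped dead time plus a single first-order
lag (one apparent time constant per sensor, as a single step test can
identify). Discrete filtering uses the exact solution of the lag ODE for
linearly interpolated input (first-order hold), which matters because the
logging interval (60 s) is comparable to the time constants involved.

**Identification.** The delay is the time from the input step to the first
of two consecutive samples departing more than 3× the baseline noise from
the pre-step baseline (the two-sample rule stops single noise spikes from
faking a departure; ≥ 5 baseline samples are required for the noise
estimate). The time constant is then fitted by nonlinear least squares to
`y₀ + Δy·(1 − exp(−(t − t_dep)/τ))`. The fit is exact on the forward
model's own output, including at 1-min sampling.

**Deconvolution.** All three methods realise the first-order inverse
x = y + τ·dy/dt after undoing the dead time:

* `regularized` (default): Tikhonov inversion of the exact discrete forward
  model on a 4×-refined grid — minimise ‖S F x − y‖² + λ²‖D₂x‖² with F the
  lag filter, S the sampling operator, D₂ the second difference and
  λ = 0.1 (dimensionless; the problem is linear so λ is scale-invariant).
  The penalty suppresses the Nyquist-frequency ringing that any pointwise
  inverse produces when signal features approach the sampling interval.
* `exact`: sample-by-sample algebraic inversion of the discrete filter;
  machine-exact on noiseless data whose sub-sample variation is linear, but
  it rings on under-resolved edges.
* `derivative`: the textbook form with a Savitzky–Golay derivative. At
  60-s sampling against ~60–90 s time constants, the wide derivative stencil
  mis-estimates fast exponential segments badly; the method is retained for
  slow signals only.

The trailing `delay/dt` samples of any reconstruction are unreliable (the
dead-time shift has nothing to advance into them) and downstream analysis
drops them. When τ/dt exceeds a configurable bound the function warns about
noise amplification but never fails.

**Gas balances.** Volumetric rates come from the inert-gas balance
F_out = F_in·(1 − y_O₂,in − y_CO₂,in)/(1 − y_O₂,out − y_CO₂,out), with molar
volume 22.414 NL/mol (0 °C, 1 atm; configurable). The forward direction
(`fractions_from_rates`) is the exact inverse and conserves inert moles by
construction.

## Physiology (`sretools.physiology`)

Biomass-specific rates use q_glc = D·(C_feed − C_residual)/(X·M_glc), gas
rates are volumetric rates divided by biomass, and uptake rates are stored
as positive magnitudes (rendered with a leading minus in report tables).
Replicates propagate elementwise; printed mean ± sd triples can be expanded
into exact moment-matched replicate sets ({m − s, m, m + s} for n = 3).

Elemental balancing uses degrees of reduction with γ(C) = 4, γ(H) = 1,
γ(O) = −2, γ(N) = −3 (ammonia nitrogen source): carbon recovery compares
CO₂ + biomass-C + other-C against glucose carbon consumed; nitrogen balances
biomass N against ammonia uptake; available electrons compare
γ_X·(biomass C-mol) + 4·(mol O₂) against 4 electrons per glucose C-mol. The
biomass composition defaults to the standard yeast C-mol formula
CH₁.₈O₀.₅N₀.₂ (γ_X = 4.2, 24.63 g/C-mol) because the source dataset does not
print its own; it is configurable.

The ATP production estimate is q_ATP = 2·q_glc + 2·(P/O)·q_O₂ with
P/O = 1.08 by default — substrate-level phosphorylation plus oxidative
phosphorylation at 2 O atoms per O₂, valid for fully respiratory
metabolism. Both coefficients are explicit arguments and the returned object
carries the formula as text, because alternative accountings (growth-coupled
corrections, other P/O conventions) shift the result by a few percent and a
bare number would be misleading.

Steady-state comparisons use Welch's unequal-variance t-test with
Satterthwaite degrees of freedom, implemented directly from the closed
formulas and cross-checked in the test suite against an independent
implementation to 1e-10; changes with p > 0.05 are rendered "n.s.".

## Metabolome (`sretools.metabolome`)

Charges are ratios of replicate means: the adenylate energy charge
(ATP + ½ADP)/(ATP + ADP + AMP) and the two reduction charges
NADH/(NADH + NAD⁺) (catabolic) and NADPH/(NADPH + NADP⁺) (anabolic), with
first-order (delta-method) uncertainty propagation when pool sds are
supplied. AxP correction factors (ATP 2.71, ADP 1.88, AMP 1.21) are applied
only on request — quantified panels normally arrive already corrected.

The relaxation trajectory analysis follows the conventional recipe:
per-metabolite min–max normalisation over the included sample set (constant
columns map to 0 by convention), Euclidean distances between samples, and
classical (Torgerson) metric MDS — double-centre the squared distances,
eigendecompose, embed on the top-k eigenvectors scaled by √eigenvalue,
k = 2 by default. Eigenvector signs are fixed deterministically (first
non-zero loading of each axis made positive) so repeated runs are
bit-identical. If fewer than k positive eigenvalues exist, fewer axes are
returned with a warning. The metabolite inclusion list is configuration, not
a hard-coded count, since published panel sizes are inconsistent (28 vs 29).
Relaxation metrics report each sample's embedding distance to a reference
sample and to an attractor sample, plus a monotone-convergence flag over a
trailing window.

## Synthetic data (`sretools.synth`)

The study's raw fermentation and metabolome data are not redistributed in
machine-readable form, so a seeded generator emulates the experiment with
known ground truth. It is a pure function of its `ScenarioSpec`: the same
seed reproduces the bundle bit-exactly, and noise settings never move the
ground truth.

* **Phases.** Reference steady state (0.5 h, initialised at the exact Monod
  fixed point), one 2-min feed stop with 30 min of continuous-feed recovery,
  then five 2/7-min cycles. Simulated at dt = 1 s.
* **Gas observables.** True volumetric rates are yield-scaled glucose uptake
  passed through first-order *biological* lags (60 s for O₂, 90 s for CO₂ —
  intracellular redox/TCA buffering; bicarbonate additionally buffers CO₂),
  plus a maintenance-respiration floor per gas. The floors are calibrated
  inside the generator so the dynamic-steady-state cycle amplitudes equal
  22.8 (O₂) and 12.3 (CO₂) mmol·L⁻¹·h⁻¹, the reported magnitudes. Without
  the biological lags the simulated glucose trough (~30 s) would be beyond
  the Nyquist limit of 1-min logging and no deconvolution could recover the
  amplitudes — the smoothness and repeatability of the published gas traces
  indicate the physical signal was resolvable. Rates are converted to mole
  fractions by the inert balance, smeared with the *apparent* line dynamics
  (delay 180 s, τ = 90 s — slower than the 55-s nominal sensors because of
  the mixing chambers), sampled on a 1-min grid offset 15 s from the cycle
  clock (instruments are not synchronised in a real rig), and given additive
  mole-fraction noise (sd 3×10⁻⁵, the repeatability class implied by the
  ±0.3 mmol·L⁻¹·h⁻¹ amplitude scatter).
* **Metabolites.** Phenomenological piecewise first-order responses: decay
  toward a famine level during feed-off, recovery toward a (possibly
  different) post-perturbation level afterwards, and an optional α-pulse
  a·x·e^(1−x) for the AMP/ADP/IMP-type overshoots. Printed levels are used
  where available (ATP 8.12 → 3.56, FBP 0.36 → 0.14, NADH 0.17 → 0.10, the
  NADP couple at total 0.36 and ratio 1.28, a 3.9-fold AMP peak, a 1.6-fold
  persistent inosine elevation); everything else is an order-of-magnitude
  synthetic placeholder. Triplicates receive multiplicative Gaussian noise
  (8% relative, the printed-sd class), truncated at zero.
* **Process measurements.** Replicate biomass, residual glucose, flow and
  ammonia readings are drawn around values constructed to close carbon,
  nitrogen and electron balances *exactly*, so the noiseless bundle is a
  fixed point of the balancing stage.
* **Step experiment.** A synthetic sensor step test (step at 600 s, 1-min
  logging) ships with every bundle so the pipeline identifies the sensors
  from data instead of trusting the config.

What the generator does **not** emulate: LC-MS/MS measurement physics,
by-product (ethanol/acetate) kinetics, large-scale hydrodynamics and CFD
lifelines (external traces can be analysed with `reactor.Lifeline` but are
never generated), biological adaptation (the metabolite model is the
non-adapted response; the DS gas phenotype is not shifted +4% against RS).
Passing tests therefore demonstrate that the *estimators* are correct and
well-conditioned under realistic noise, not that the biology of a real
culture is predicted.

## Pipeline and problem sizes

`run_pipeline` executes: sensor identification (if a step file is present) →
deconvolution → gas balances → steady-window rate estimation → recoveries
and the RS/DS comparison table → charge series → min–max/distance/MDS →
relaxation metrics, writing CSV tables, a JSON summary and a plain-text
report. Runs are deterministic; byte-identical inputs give byte-identical
outputs. The steady-state window excludes a margin of (delay + 2τ) before
the first transition because the global regularized deconvolution can
pre-ring slightly ahead of an edge.

Default problem sizes (0.5 h reference phase, 30 min recovery, 5 cycles,
triplicates) keep a full generate-analyse cycle under a second on one core;
they are the package's chosen balance between statistical stability of the
cycle-amplitude estimates (5 complete cycles) and quick iteration. All
sizes scale through `ScenarioSpec`.

## Known limitations

* Monod kinetics cannot reproduce the reported *slowing* of glucose
  depletion near the starvation boundary (the published trough of
  22 µmol/L vs < 10 µmol/L predicted): with C* fixed by the supply balance,
  the deep-limitation decay constant q_max·X/K_M is pinned. The
  `uptake_scale` argument reproduces the "60% of anticipated kinetics"
  comparison but is a description, not a mechanism (trehalose recycling and
  transport effects are out of scope).
* The deconvolution assumes one lag per channel; a chain of mixing chambers
  would need a higher-order model and a richer identification experiment.
* Recoveries assume steady state within the averaging window; the transient
  30-min window after a perturbation can legitimately deviate by a few
  percent, as the published balance tables themselves show.
* Welch tests on n = 3 replicate sets reconstructed from mean ± sd are
  exact in their first two moments but cannot recover the original
  replicate correlation structure.
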