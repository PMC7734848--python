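# Methods

## Model class

The engine implements Extended Stochastic Symmetric Nets (ESSN): stochastic
Petri nets whose tokens may carry a color from a finite, circularly ordered
class, and whose transitions split into *mass-action* ("standard")
transitions — propensity = rate constant x product of input token counts
raised to arc multiplicities — and *general* transitions with arbitrary
nonnegative rate functions of their own input places and time.  Colored
transitions are ground-instantiated ("unfolded") into plain reactions before
any analysis; guards filter bindings at unfold time.  The folded structure is
retained for structural reporting, so place/transition counts are folded
counts.

Three behavioural semantics are derived from one reaction list:

* **Exact SSA** (Gillespie direct method): exponential waiting time with the
  total propensity, categorical choice proportional to individual
  propensities.  Scheduled interventions (antigen or drug injections) are
  deterministic token additions applied exactly at their times; because the
  exponential law is memoryless, the waiting time is simply redrawn after
  each event.
* **Tau-leaping**: fixed leap `tau`, Poisson(a_r tau) firings per reaction,
  leaps truncated at event boundaries.  If a leap would drive a count
  negative the step is halved and redrawn (the step shrinks until all draws
  are zero, which always succeeds), so integer states never go negative.
* **Fluid (ODE) limit**: dx/dt = sum_r L_r a_r(x), dimension = number of
  dynamic (place, color) variables.  The public integrator wraps scipy's
  LSODA with event restarts and zero-clipping (rtol 1e-6, atol 1e-9
  defaults); calibration uses an internal adaptive Dormand–Prince RK45
  compiled with numba (~0.1 ms per 3-day solve), which tests verify against
  LSODA to interpolation accuracy (~1e-4 relative).

For small nets the master equation is solved exactly: breadth-first
enumeration of the reachability set (explicit overflow error beyond a cap),
sparse generator assembly from the propensities, and a Krylov
matrix-exponential action for the transient distribution.  This is a test
oracle — the SSA's empirical distribution is checked against it by
chi-square — not a production path; the state space of the disease model is
astronomically larger than any enumerable set, which is why the simulation
backends exist.

Randomness: every simulation takes an explicit seed; ensemble members derive
their seeds from `(master seed, trajectory index)` only, so two ensembles
with the same master seed share common random numbers trajectory-by-
trajectory.  The kernels draw only uniform variates from the numpy legacy
MT19937 stream (tau-leap Poisson variates are generated from uniforms via
Knuth's product method below mean 10 and Hörmann's PTRS rejection above), so
a seed reproduces a trajectory bit-for-bit whether or not the jit compiler
is available.

## The RRMS network

Two compartments — peripheral lymph node / blood, and CNS — joined by the
blood–brain-barrier place `BBB`, whose tokens count permeability quanta:
IL-17 creates them (barrier damage, rate `p_BBB_damage * IL17_out`), IL-10
removes them (repair, `p_BBB_repair * IL10_out * BBB`), and they reseal
spontaneously (`p_bbb_decay`).  Effector and regulatory T cells cross at
`p_pass * cells * BBB` and arrive as *resting* CNS cells that need a second,
IFNg-driven activation (`p_act * resting * IFNg_in / (k_half + IFNg_in)`).
Peripheral activation is antigen-driven with the same saturating form.
Cell–cell killing (Treg on Teff, NK on Teff) saturates in the target
(`rate * killer * target / (k_half + target)`); daclizumab depletion of
activated Teff and Treg is bilinear (`potency * DAC * target`), consuming
ten drug tokens per depleted cell, with first-order elimination of unbound
drug.

Oligodendrocytes are one colored place over the ordered class
`Mye = (Lmin, L1, L2, L3, Lmax)`.  All 500 start at `Lmax` (fully
myelinated).  `TeffKillsODC` (guard `l not in {Lmin}`) moves one token one
level toward `Lmin` at `p_Teff_kills_ODC * Teff_in` per attackable token;
`Remyelinization` (bindings `L1..L3`) moves one level up.  No transition
consumes an `Lmin` token, so irreversible damage is absorbing — the
model's disability readout is the `Lmin` count.

The folded net has 26 places and 55 transitions (40 mass-action, 15
general).  The published description names 45 transitions and the main
cell/cytokine places; the remainder is reconstructed housekeeping, each
flagged `reconstructed: true` in the model structure and the shipped model
file: deaths of effector/resting/memory pools, antigen decay, BBB
resealing, memory re-activation (mass action in memory cells and antigen,
~10x faster per cell than naive priming, reflecting the faster recall
response), a thymic source of naive effector cells (the resting pool
regenerates with a ~2-month timescale, so successive relapses meet a
recovering repertoire), a slow basal re-activation of CNS resting
effector cells standing in for antigen-presenting contact (the
IFNγ-driven pathway then amplifies it during relapses), and four
arc-less annotation places (thymus, NK source, drug source,
antigen sink) that carry no dynamics.  Excluding those annotation nodes the
fluid limit has exactly 26 equations (21 neutral places + 5 myelination
levels).

Time unit: days (18 h = 0.75 d).  Counts are cells (or tokens) per mm^3.

## Calibration

Targets are the printed group-summary rows of the reference cohort table
(8 MS patients, 8 healthy donors; IFNg-, IL-17- and IL-10-producing cells
per mm^3 in blood and CSF).  A few printed summary cells are not the
arithmetic mean of their column (the per-column statistic used originally
is not stated); the printed values are therefore taken verbatim as targets,
while `group_targets` recomputes means/medians from per-subject rows for
synthetic cohorts.

The fit minimises 12 epsilon-guarded relative residuals
`(model - target) / (target + 1)` — the readout at day 2.75 after a
100-copy antigen injection at day 2, for both groups jointly — over 22
log-scale parameters: 18 shared constants plus (`p_Teff_Activation`,
`p_Treg_Activation`) per group.  Sharing everything but the activation pair
*builds in* the finding that health and disease differ only in activation
balance, rather than checking it post hoc; the direction of the difference
(effector up, regulatory down in MS) is left to the optimizer and is
asserted by tests, not imposed.

Three auxiliary terms make the problem well-posed (12 observations cannot
pin down 22 constants):

* a **stability residual**: the largest live count at days 5, 10 and 30
  must stay below 2.5e3 cells/mm^3 — without it the global optimum runs
  away (duplication >> death) and the course diverges after the readout;
* a **remission residual**: activated T cells at day 30 must have fallen
  below 200 — the disease is relapsing–*remitting*, and a single antigen
  challenge must resolve within the calibration window;
* a weak **log-scale ridge** (weight 0.002 per parameter) toward the
  documented default magnitudes, selecting a plausible member of the
  near-equivalent optimum family.  The shipped defaults are the reference
  calibration's own magnitudes (rounded), so the default start converges
  to the reference solution quickly; the same solution family is found
  from random starts alone, only more slowly.

The reported `loss` is always the pure target part.  Optimization is
multi-start (Latin hypercube on log10 scale, deterministic per seed)
trust-region-reflective least squares; integration failures and blow-ups
return penalty residuals, which prunes pathological corners cheaply.

The packaged `reference_fit.json` is the output of this pipeline
(`fit(targets=printed rows, n_starts=8, seed=1)`); it reproduces every
printed analyte within a few percent and yields the expected phenotype
(ODC damage and peak BBB permeability markedly higher in the MS
configuration; essentially none in the healthy one).

**Parameter recovery.**  Virtual patients push a known configuration
through the same readout, optionally with multiplicative log-normal
observation noise.  Because the joint problem is underdetermined, recovery
is assessed as a *profile* question: with the 18 shared constants pinned at
truth (`fit(shared_fixed=...)`), are the two activation constants per group
identifiable from the six analytes?  Noiseless targets are recovered to
well under 5%; with 10% observation noise the median error over replicates
stays under 20%.

## Therapy scenarios

The two-year study imposes eight 100-copy antigen injections (days 2, 67,
127, 295, 300, 303, 307, 600) on the calibrated MS configuration.
Daclizumab is injected every 28 days at a fixed dose (1000–15000 drug
tokens) and potency (0.01 weak / 0.03 strong, applied to both the Teff- and
Treg-kill reactions), starting at day 30 ("early") or day 180 ("late").
Drug units are eliminated first-order with a ~5-week half-life, so
coverage is continuous across the 28-day cycles, and each depleted cell
consumes ten drug units — the injected dose therefore bounds how many
effector and regulatory cells a cycle can neutralize, which is what makes
dose a graded protective variable rather than an on/off switch.

Endpoints per trajectory: irreversibly damaged ODC count at day 730, and
the trapezoidal area under the antigen curve over the whole horizon.
Ensembles use SSA (the exact backend) with common random numbers across
scenario cells; summaries are median and interquartile range on a daily
grid.  Tau-leaping is available behind a flag for exploratory runs; its
accuracy against SSA is exercised in the test suite on small systems.

The default ensemble size is 1000 trajectories; the shipped test suite and
reproduction script run 100–200 trajectories per scenario, a problem size
chosen to keep a full desk run in minutes while leaving the qualitative
comparisons (damage non-increasing in dose, antigen burden non-decreasing
in dose, early regime protecting more than late) statistically resolvable.

## Synthetic cohorts

Cohort tables are emulated with independent per-analyte log-normal
marginals, moment-matched on the log scale per group — reproducing the
strict positivity and heavy right skew of the real counts (blood IFNg
spans more than an order of magnitude across MS patients).  The generator
does **not** model inter-analyte correlation (the reference table gives no
basis to estimate it), longitudinal structure, or measurement error of the
cytometry itself; passing recovery tests on synthetic cohorts therefore
demonstrates pipeline correctness, not robustness to those real-data
features.  Virtual patients are generated at the group-mean (ODE) level,
matching the group-level calibration.

## Numerical and degenerate-input conventions

* ODE nonnegativity: states are clipped at zero after each integrator
  step; clips beyond `atol` are counted in trajectory metadata.
* Mass-action propensities use `count^multiplicity` with an enabling check
  (`count >= multiplicity`), so a reaction needing 2 tokens of a place with
  1 has propensity zero even though 1^2 = 1.
* Ties in the event schedule are applied in schedule order; a grid point
  that coincides with an event time records the post-event state
  (right-continuous paths) in every backend.
* Zero-propensity systems stay constant to the horizon in all backends.
* The SSA caps steps (default 2e8) and raises rather than spin on runaway
  configurations; tau-leap's step-halving is bounded and degenerates to a
  no-op advance rather than looping.
* `dac_schedule` with a start day beyond the horizon warns and returns an
  empty schedule; `antigen_schedule` rejects unsorted days.

## Known limitations

* The functional forms and many fixed constants of the interaction
  transitions are this package's documented defaults (configuration-
  replaceable), reconstructed from the narrative description; quantitative
  trajectory shapes are therefore not comparable figure-by-figure with the
  original study, and the scenario analysis is interpreted through ordinal
  properties (dose monotonicity, early-vs-late ordering), which are robust
  to those choices.
* Group-level calibration only: no per-patient fits, no identifiability
  or sensitivity analysis beyond the profile-recovery harness.
* B cells, NK subtypes, vitamin-D effects and spatial structure within
  compartments are outside the model's scope.
* Drug dose is in abstract drug-unit tokens; no pharmacokinetic model
  beyond injection plus first-order elimination is attempted.
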