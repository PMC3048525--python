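# Methods

## Model structure

The network couples three layers at different time scales.

**Slow layer (stochastic).**  Protein synthesis and degradation are sampled
exactly with the Gillespie algorithm.  Transcription and translation are
collapsed into one reaction: each synthesis event adds a burst of proteins
with mean `b = 2.5`.  Because the published burst factor is fractional, the
default draw is 2 or 3 molecules with probability ½ each (mean 2.5), keeping
counts integral; a fixed-2.5 fractional mode (`burst_fixed`) exists for
validation against the analytic birth–death limit.  Each of the 11 protein
species decays at `γ = 0.002 s⁻¹`; complexes (Gal3-80p, Gal1/3-80p,
Gal4-80p) are degradable species in their own right and are removed whole,
with no dissociation products.  Gene copy number multiplies the synthesis
propensity — equivalent to duplicating the reaction channel.

**Fast layer (deterministic).**  Galactose transport is algebraic and
unconsumed: `gal_in = gal_out (a + b·Gal2p)` with `a = 0.001`, `b = 0.01`
per Gal2p molecule; intracellular galactose is clamped to this value at
every deterministic step and appears catalytically in the activation
reactions.  The five reversible mass-action reactions (activation of Gal3p
and Gal1/3p by galactose; binding of Gal80p by the two active co-inducers
and by Gal4p) are driven to their joint equilibrium between stochastic
events without advancing the simulation clock.  Given the four conserved
family totals the equilibrium of this reaction network is unique, so instead
of integrating the stiff ODE system we solve the scalar balance equation for
free Gal80p — a strictly monotone function — by bisection (80 iterations,
machine-precision), and fill in the other eight species in closed form.
Numerical ODE integration (scipy, LSODA) serves as an independent oracle in
the test suite; the two agree to 1e-5 relative on random pools.

As a performance approximation the deterministic step executes every *n*-th
Gillespie iteration, with `n = max(1, total deterministic molecules /
det_skip_scale)` and `det_skip_scale = 1000` by default.  Endpoint means are
unchanged across a 10× range of this constant (tested); the rationale is
that synthesizing or degrading a few molecules cannot move an equilibrium
involving thousands.

**Promoter layer (thermodynamic).**  Each UAS is empty, Gal4p-bound or
Gal4-80p-bound.  For occupancy configuration *c* with `n4` activator-bound
and `n480` repressor-bound sites, the statistical weight is

    w_c = ([Gal4]/c0)^n4 ([Gal4-80]/c0)^n480 · exp(−ΔG_c / β)

with the all-empty configuration as zero-energy reference, `ΔG_bind =
−13.86 kcal/mol` per occupied site, and cooperative terms for adjacently
bound like pairs on the in-phase promoters (GAL1 pairs (0,1),(1,2); GAL2
pair (0,1); mixed adjacent pairs contribute nothing).  The propensity is the
weighted mean of the per-configuration contribution sums `K_c`, clamped at
zero because basal contributions can be negative (active repression).  A
promoter with no UAS (GAL4's) is constitutive.

## Units and calibration

The published rate constants carry no units, and taken literally the
published exponent convention would make favorable binding energies
*destabilizing*; both must be fixed by choices.  Ours, validated against the published *S. cerevisiae*
equilibrium table by a mean-field fixed-point analysis of the full model:

* **Boltzmann weights** use `exp(−ΔG/β)` with `β = 1.68 kcal/mol` as
  published, so negative ΔG stabilizes occupancy.
* **Protein–protein mass action** interprets the published rate constants per
  **nanomolar** at the 23 fL cellular volume.  This is not arbitrary: fitting
  the unit scale as a free parameter against the published equilibrium counts
  recovers 0.070/molecule, and 1 molecule per 23 fL = 0.072 nM.  Galactose
  activation keeps molar units (`K = 10 M⁻¹` as published).  With molar units
  throughout, association at nanomolar protein concentrations would be
  negligible and the switch would not function at all.
* **TF activities** in the promoter weights use nuclear-volume (1.66 fL)
  concentrations against a reference `c0 = 1.02e-2 M`, calibrated once; the
  equivalent per-site dissociation constant is `c0·exp(ΔG_bind/β) ≈ 2.7 µM`.
* **synthesis_scale = 10** multiplies all promoter propensities.  The published
  constants imply a constitutive Gal4p mean of `0.06·2.5/0.002 = 75`,
  tenfold below the published ~755; the factor is pinned exactly by that row
  of the equilibrium table.  It is treated as a pure change of molecule
  units: TF counts entering promoter weights are normalized by
  `synthesis_scale/scale_reference` (reference 10), so fold-changes and
  ratios are invariant to it apart from demographic noise.
* **Cooperative energies.**  The cooperative energies were originally
  chosen by calibration against network behavior, not measured.  Under our
  sign-corrected weights the published Gal4p-pair value (−2.00 kcal/mol) is
  kept, but the published repressor-pair value (−3.00) cannot produce the
  ~105-fold GAL1 switch; the effective default is **−5.60 kcal/mol**,
  refitted once against the same equilibrium table.  Both energies remain
  configuration keys.

With these defaults and 10–30 replicates the model reproduces (published
value in parentheses): Gal1p fold-induction ~107 (105), Gal3p-family fold
~5.5 (5), Gal80p-family fold ~7.0 (6), Gal4p fold ~1.0 (1), ancestral
galactokinase fold ~4.9 (6), ancestral uninduced co-inducer ~32,000
(~27,000), uninduced/induced Gal3p:Gal80p ratios ~5.9/4.7 (5.26/4.60).
The ancestral-network quantities trade against the GAL3/GAL80 folds through
the single global TF-weight scale; the default is the minimax compromise,
leaving both about 15–20% from their targets.  GAL2's fold-induction
(~21 vs ~118) is the largest known residual: its uninduced expression runs
high, which inflates uninduced galactose import; downstream contrasts are
insensitive to this because uninduced activation stays far below threshold
either way.

## Simulated experiments

Simulations start from an empty cell (zero proteins — a modeling choice;
the equilibration burn-in completes long before sampling) and run 8000 s, many multiples of the
500 s protein lifetime; endpoints are equilibrated (verified out to
16,000 s).  The "equilibrium distribution" is the set of endpoint counts
over independent seeded replicates — endpoint sampling, not time-averaging.
Replicate seeds derive from a single SeedSequence per run, and feature
sweeps key each network's stream by its copy-number vector, so results are
independent of enumeration order and bit-reproducible given (configuration,
parameters, seed).

Features: repression strength = galactokinase count (Gal1p + Gal1/3p
family) at 10⁻⁸ M galactose; induction strength = the same count at 0.1 M;
switch effectiveness = co-inducer count (Gal3p + Gal1/3p families) at
10⁻⁸ M.  Counts include complexed forms by default (what a fold-induction
assay reports); `include_complexes=False` gives the free-forms-only
sensitivity mode.

Path scoring uses one cached feature estimate per (network, feature) from a
single 33-network sweep, as in the original analysis; ties with the best
alternative incur zero penalty.  The "events separating the two
specializations" covariate counts strictly intervening events (0–3); the
inclusive positional-distance convention is available because the published
axis is not defined numerically.  Two-sample contrasts default to Welch's
unequal-variance t-test ("two-sample t-test" is otherwise ambiguous); the
pooled form is a flag.

Perturbation analysis draws one independent factor per parameter within
each published class (a single shared factor per class would cancel in the
forward/reverse rate ratios and perturb nothing): mass-action rates and
transport coefficients ×10^U(−1,1); degradation rate and burst ×2^U(−1,1);
contribution entries and constitutive rates ×2^U(−1,1); binding and
cooperative energies +U(−1,1) kcal/mol.  Perturbations are non-persistent —
every intermediate network redraws from the base parameters, *S. cerevisiae*
is never perturbed, and the base object is immutable.  A replicate whose
perturbation collapses a feature to zero is flagged as having abolished
switch behavior and recorded, not fatal.

## Problem sizes

Default replication follows the original study design (100 replicates, 8
galactose concentrations) but every entry point takes `n_replicates`/`t_end`.  The
test suite runs scaled-down versions chosen once: the 33-network feature
sweep at 10 replicates and 4000 s (equilibrated well before), perturbation
dispersion at 10 replicates × 1 feature replicate × 1500 s, and the
induction contrasts at 12 replicates of the full 8000 s.  The acceptance
script uses 32 replicates of 8000 s.

## Known limitations

* Absolute molecule counts match the published table only to ~±20% for some
  species (see calibration); fold-changes and ratios are the reliable
  outputs.
* The GAL80-loss-last group of paths scores better than the rest on
  repression (direction and significance reproduce), but its mean penalty
  is deeper than published (−1.8 vs −0.34): this model's repression
  landscape penalizes early-step choices within that group more strongly.
* The repression- and induction-optimal orderings contain near-ties
  (S1/S3 and L2/L4 transpositions, penalties < 0.05 dex), so the exact
  argmax path is seed-dependent at finite replication.
* No galactose catabolism downstream of Gal1p, no glucose repression, no
  mRNA species, no cell growth or division, and no fitness interpretation
  of the features.
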