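# Methods

## Model structure and assumptions

The package models the nAcRβ2/SKIP/Shal/miR-1010 motif as a well-mixed,
deterministic mass-action system with eight species (receptor mRNA `R`,
surface receptor `P`, potential proxy `V`, phosphorylated Adf-1 fraction
`A`, SKIP transcript `St`, functional SKIP protein `Sp`, Shal channel `K`,
mature miR-1010 `M`). The governing equations are listed in the README
and assembled reaction-by-reaction in `mirloop.kinetics`; the modelling
choices behind them are:

* **Potential as a scalar activity proxy.** `V` is a dimensionless,
  long-term average of the membrane potential with resting level 0, not an
  electrophysiological waveform in mV. No spatial or compartmental
  structure and no stochastic (Gillespie) channel noise are modelled.
* **Adf-1 as an activity-driven transcriptional driver.** Biologically
  Adf-1 pauses SKIP/Shal transcription until phosphorylation releases
  them; at this level of abstraction de-repression and activation are
  equivalent, so the phospho-fraction `A` (conserved total of 1) directly
  drives SKIP, Shal and mirtron production. The phosphorylation term
  `k_Aon·V·(1−A)` is mass action on the conserved unphosphorylated pool.
* **Mirtron–host coupling.** miR-1010 is spliced from a SKIP intron, so
  its production is stoichiometrically tied to SKIP transcription with
  yield `eta ∈ [0, 1]` (`dM/dt = eta·a_S·A − d_M·M`). This is what lets a
  translation-blocking cassette (SKIP-MiMIC) abolish SKIP protein while
  leaving mirtron output intact, and what couples host and mirtron
  dosage in the heterozygote.
* **Catalytic miRNA repression**, first order in both `M` and `R`
  (standard miRNA kinetics; the miRNA is not consumed).
* **SKIP action as amplification of Shal tempering.** The repolarizing
  term is `g_K·K·(1 + alpha·Sp)·V`: Shal tempers on its own, and
  functional SKIP protein multiplies that tempering (slow-inactivation
  mode), implemented as two elementary reactions sharing `g_K`.
* **Time unit.** `d_P` defines the clock: one time unit is one receptor
  lifetime `1/d_P`. Multiplying every 1/time constant by `c` and
  rescaling time by `1/c` leaves trajectories invariant (tested); the
  dimensionless `eta` and `alpha` do not scale.

## Default parameters

All defaults are dimensionless, order-one values; they are defaults, not
fitted estimates, and every one can be overridden from the YAML/JSON
config. Productions/gains: `k_R=1, a_R=2, k_P=1, k_V=2, k_leak=1, g_K=1,
alpha=4, k_Aon=2, k_Aoff=1, a_S=1, k_Sp=1, a_K=1, eta=1`; decays 1.0
except `d_M=0.2`; repression `k_rep=6`. The repression strength and
miRNA decay were chosen (by a coarse grid scan over `k_rep × d_M × a_R`,
before any test was written against the outcome) as the values at which
the motif exhibits the qualitative regime structure the model exists to
reproduce: wild-type returns below 20% of its peak within a few receptor
lifetimes, half mirtron dosage and SKIP-protein loss return with a
positive delay and overshoot the wild-type peak, and complete mirtron
loss stays active through a 50-lifetime horizon. With slower miRNA decay
or weaker repression the baseline miRNA level is too high a fraction of
its dynamic range and even the wild type plateaus above threshold; the
shipped values leave headroom for the feedback to act.

Perturbation magnitudes unconstrained by direct measurements default to
`extra_depolarization=1` (NaChBac, same order as the stimulated drive),
`leak_scale=3` (Kir2.1) and `agonist_gain=2/4` (nicotine low/high dose);
calibration may refit them.

## Stimulus, initial conditions and solver

Receptor activation is by default a **unit step at t=0** (sustained
agonism); pulse and narrow-impulse (width 0.05 lifetimes, unit-area
scaled) profiles are available. Each genotype starts from the resting
(u=0) steady state of **its own** perturbed network — each line develops
at rest before stimulation — so `V(0)=0` for every line without a
constitutive current (NaChBac rests above 0 by construction).
Integration uses LSODA with rtol 1e−8 / atol 1e−10, ≥2001 output points
per horizon, split at stimulus discontinuities so the solver never steps
across them. Horizons: 10 lifetimes is ample for plots; 50 lifetimes
operationalizes "long-term" for Δt, terminal levels and the
sustained/returning classification.

Steady states are found by a closed-form reduction for the canonical
topology (all species are explicit functions of `V`; the scalar balance
for `V` is bracketed and solved by Brent's method, residual verified
against the full right-hand side at < 1e−9), with Powell hybrid
root-finding and relax-then-polish integration (up to 500 lifetimes) as
fallbacks for non-canonical networks. A provable runaway — receptor
drive outgrowing every tempering term as the phospho-fraction saturates —
raises an explicit no-steady-state error rather than timing out.

## Metrics

`t_return` is the first output-grid time at or after a curve's own peak
from which the normalized potential stays below `threshold` (default 0.2,
i.e. 20% of the wild-type peak) for the entire remaining grid; no
debounce window is used because deterministic ODE output cannot chatter.
A curve whose peak is already below threshold "returns" at its peak time.
`delta_t` is the difference to the wild-type's own `t_return`; a response
with no `t_return` within the horizon is *sustained*, a positive delay is
*delayed*, otherwise *homeostatic*. The wild-type peak used for
normalization is the global peak over the simulated window. The switch
scan classifies responses over an η grid (≥11 points) and reports the
smallest returning η together with a monotonicity flag; non-monotone
grids are reported as such, never silently repaired.

## Calibration

`SynapticHomeostasisModel.fit` minimizes `Σ w·(log2 pred − log2 obs)²`
over steady-state fold changes at constant drive u=1, with unit weights
("~" printed values are treated as exact targets; no uncertainties are
published to weight by). The rescue-line SKIP ~10-fold row ships with
weight 0 — the observation is explicitly unexplained — and conditions
without a model counterpart (rescue line) never enter the loss. Search is
seeded multistart (≥5 starts) Nelder–Mead on log-parameters inside a
[0.01, 100]× box; decay rates are excluded from the default free set to
preserve the time unit. The default free set is `a_R, k_rep, g_K, alpha`
plus the nicotine agonist gain and the Kir2.1 leak scale. The search
objective additionally carries a soft quadratic barrier on the published
qPCR signs (receptor mRNA ≥2-fold in the miRNA null, repressed under
NaChBac, raised under Kir2.1, mirtron raised in the binding-site mutant),
so a fit cannot buy least-squares loss by inverting a printed direction;
the reported `loss_value` is always the pure weighted residual sum and is
recomputable from the residual table. One structural misfit is expected
and visible in the residuals: with the phospho-fraction bounded at 1, the
mirtron's dynamic range above its baseline is capped, so the ~10-fold
nicotine miR-1010 induction is only partially attainable (the fit
reaches ~5-fold and pushes the agonist gain to its bound); the 2-fold
receptor induction, 1.24-fold Kir2.1 and ~3-fold null observations are
matched closely.

## qPCR pipeline

Quantification is the standard endogenous-control route: per-replicate
ΔCt = target − reference (Rpl32 for mRNA, U27 for miRNA), ΔΔCt =
mean ΔCt(condition) − mean ΔCt(control), fold change 2^−ΔΔCt; SDs are
reported per group from replicate ΔCt values. Amplification-efficiency
correction is out of scope (no efficiencies are published). The
expression filter (mean control-group target Ct strictly < 33 cycles)
flags whether a target is expressed at meaningful levels. Significance
follows the published decision rule on the ΔCt scale (the statistically
standard choice; testing fold changes directly would be the alternative):
Bartlett's variance-homogeneity test at α=0.05 gates a pooled-variance
Student t test versus Welch's t test with Satterthwaite df, both
two-sided, with both branch p-values reported. No multiple-testing
correction is applied. Stars follow the 0.05/0.01/0.001 convention.

## Synthetic data: what it does and does not emulate

The generator draws independent Gaussian cycle noise (default SD 0.2
cycles, typical technical qPCR variability) around a baseline target Ct
of 24 and reference Ct of 15, shifting the condition group's target mean
by −log2(true fold change); nine replicates per group mirror the
published replication level. Ground truths are the published fold
changes. This validates the quantification arithmetic, its statistical
calibration and the Monte-Carlo unbiasedness of the log2 estimator. It
deliberately does **not** model batch structure (biological vs technical
replicate nesting), amplification-efficiency differences between target
and reference, melt/amplification curves, or Ct-dependent
heteroscedasticity — so passing tests certify the pipeline, not the
noise structure of any real instrument.

## Numerical choices and degenerate inputs

Species are clipped at 0 within solver tolerance (1e−8) on output;
states violating non-negativity beyond tolerance, Ct values outside
(0, 40], groups with fewer than two replicates, zero-variance equal-mean
t-test inputs, a zero wild-type peak at normalization, and a wild-type
that never returns below threshold (a misconfigured default set) all
raise typed errors rather than producing numbers. Identical constant
groups in quantification return fold change 1 with p=1 (no evidence of
change). Fold changes against a wild-type steady state below 1e−12 raise
a degenerate-reference error.

## Known limitations

* The nicotine dose–response non-monotonicity (lower mirtron induction at
  the higher dose, with behaviourally impaired larvae) is outside a
  well-mixed model without a toxicity/saturation term and is not modelled.
* Rescue-line Gal4/UAS overexpression mechanics and neuron-type spatial
  specificity are out of scope; the rescue SKIP observation is carried as
  data only.
* Drl-2 and CG3078 are treated as qPCR observables, not dynamical
  species.
* The bounded phospho-fraction caps the mirtron induction range (see
  Calibration), a structural property of the single-sensor design rather
  than a numerical artifact.
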