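# Methods

## Model structure

The model couples 29 continuous state variables to five instantaneous
threshold events.  Concentrations are dimensionless arbitrary units (a.u.)
matched to the packaged initial-value table; time is in minutes throughout.

**DNA layer.**  Replication initiation progress `Ini` integrates a
DnaA-activated, CtrA∼P-inhibited rate (Hill exponent 4 on both, scaled by
Θ_DnaA and Θ_CtrA) multiplied by a methylation boost
`1 + 1/(J_i,Ini⁴ + (h_Cori/Θ_Cori)⁴)`: a fully methylated origin (h_Cori = 0)
accelerates initiation ~1.2-fold relative to a hemimethylated one.  When
`Ini` reaches P_elong = 0.05 the initiation event fires: `Ini` resets to 0,
fork progress `Elong` restarts, the origin becomes hemimethylated
(h_Cori := 1), the chromosome count doubles and the Z-ring clock switches on.
`Elong` then rises at k_elong = 6.53×10⁻³ min⁻¹ (times a Hill factor that is
≈1 away from 0), crossing the *ccrM* locus at 0.2 and the *ctrA* locus at
0.375 (each crossing sets that locus hemimethylated), and terminating at 1.
The Z-ring variable is a linear clock, dZring/dt = k_s,Zring ∈ {0, 0.011};
constriction at Zring = 1 marks division.  Note an intrinsic timing fact of
this parameterisation: full elongation takes at least
(1 − 0.1)/k_elong ≈ 138 min, whereas the Z-ring clock fires 90.9 min after
initiation, so termination always *follows* constriction within a cycle; the
event order every settled cycle is initiation → ccrM passage → ctrA passage →
Z-ring → termination.

**Gene expression.**  Each regulator has an mRNA balance with Hill-regulated
synthesis and first-order decay, and a protein balance with mass-action
synthesis from its mRNA.  Hemimethylation gates transcription: the *ccrM*
intermediate (I_ccrM, a delay stage) and the GcrA-driven P1 promoter of
*ctrA* are multiplied by their loci's h variables, and *dnaA* transcription
carries the gene-dosage factor (2 − h_Cori).  Hill exponents are fixed
integers as the model defines them (4 for the DNA-layer and CtrA/SciP
inhibition terms of *ctrA* P1, 2 elsewhere) and are not configuration knobs.

**Proteolysis hierarchy.**  ClpXP (constant pool, concentration 1) primed by
unphosphorylated CpdR forms Complex 1, which degrades CpdR, RcdA and PdeA
through Michaelis terms `[S]·C1/(J_d + C1)`; Complex 1 + RcdA forms
Complex 2; Complex 2 binds two c-di-GMP (the cdG variable stands for the
PopA:2cdG species) to form Complex 3, which degrades CtrA and CtrA∼P through
`C3²/(J_d² + C3²)`.  cdG is produced by PleD (saturating in cdG) and
hydrolysed by PdeA; cdG inhibits the CckA kinase, closing the loop between
proteolysis and CtrA phosphorylation.  The CckA pool is conserved
(0 ≤ CckA∼P ≤ CckA_T).

**PleC forcing.**  PleD dephosphorylation is driven by a PleC time course
fitted as 80.09·sin(0.013t + 1.74) + 78.77·sin(0.013t + 4.85) (radians).
The two sinusoids nearly cancel (resultant amplitude ≈ 2.8 a.u., value 0.92
at t = 0) and the raw sum is negative over most of its 483-min period.  A
negative phosphatase level is unphysical and destabilises the pool
(integrating the raw sum in absolute time drives PleD, then cdG, negative
and the system diverges), so inside the dynamics the forcing is **rectified
at zero** and its clock **restarts at every division event**.  Two
quantitative checks anchor this convention: the packaged initial state's
PleD∼P/PleD ratio (1.26) matches the phospho-equilibrium implied by the
forcing value at t = 0 (1.20), and the rectified per-cycle forcing is the
variant that reproduces the calibrated 150-min wild-type period and the
knockout periods.  `plec_level()` exposes the raw fitted sum; the rectified,
division-anchored version lives in the integrator kernel.

**Complex 3 binding stoichiometry.**  The cdG balance uses the same
second-order binding flux k₃⁺·cdG²·C2 as the Complex 2/3 balances.  This is
also self-consistent with the packaged initial state: Complex3(0) = 3.407
sits at the quasi-equilibrium k₃⁺·cdG²·C2/k₃⁻ = 3.60, whereas a first-order
flux would put the initial state far off equilibrium (dcdG/dt ≈ −8 a.u./min)
and shift the wild-type period off its calibration target.

**Elongation restart value.**  Because replication is bidirectional, the
initiation event sets Elong := 2·P_elong = 0.1 (default); the alternative
convention 0.05 is available through the `elong_at_initiation` parameter
(it lengthens the wild-type period to ~151.1 min).

## Numerics

* Solver: LSODA (stiff-capable, adaptive), rtol 1e-8, atol 1e-10,
  max step 5 min, dense output sampled at ≤ 1 min.
* Events: each integration segment ends at the first *armed* upward
  threshold crossing (a rule is armed only while its trigger variable is
  below threshold, which yields once-per-cycle semantics without explicit
  guards); crossings are located by root-finding on the dense output;
  assignments are applied atomically and the solver restarts with fresh
  state.  Simultaneous crossings resolve in event-table order.  Event times
  are invariant (±0.01 min) under tolerance halving (tested).
* Integration overshoot below zero beyond −1e-7 a.u. is treated as failure;
  smaller overshoot is clipped to 0 in the stored trajectory.
* The right-hand side is JIT-compiled (numba); a plain-Python term-by-term
  transcription in the test suite serves as a two-implementation oracle
  (agreement to 1e-12 relative at random valid states).
* The cycle period is the mean inter-initiation interval after discarding
  two transient cycles (the reference event is replication initiation, which
  occurs exactly once per cycle; division events give the same period at
  steady state), with a convergence flag requiring the last two intervals to
  agree within 1 %.  Benchmarks that quote settled periods use 6000-min runs
  with ten discarded cycles.
* Phenotype classes: *arrested* — fewer than 3 initiation events;
  *damped* — the period has not converged while the total-CtrA amplitude has
  fallen below 10 % of the first cycle's and is still shrinking;
  *oscillatory* otherwise.  A converged limit cycle with small CtrA
  amplitude (e.g. the *gcrA* knockout, whose CtrA collapses because P1
  requires GcrA) counts as oscillatory.
* QSSA variant: Complex 3 is replaced by its algebraic steady state
  k₃⁺·cdG²·C2/k₃⁻.  This preserves the period to −2.3 % and the CtrA phase
  (correlation 0.80 over a phase-aligned cycle) but shaves CtrA amplitude
  roughly twofold, because the instantaneous equilibration overestimates the
  proteolytic flux mid-cycle.

## Observations and fitting

* Observables are what blots measure: totals over phospho-forms for CtrA,
  CpdR and PleD; the 15 fit species are the five mRNAs and ten proteins of
  the observation tables.
* Normalization: per-species min–max to [0, 1], then affine rescaling to a
  per-species target range.  The published per-species ranges are not
  tabulated, so fixtures default to the sampled simulation min/max — which
  makes normalize∘rescale the identity and a noiseless self-fixture's
  misfit exactly zero.  The absolute value of f1 against real data depends
  on this unpublished scaling; only fixture-based f1 values are meaningful
  here.
* The synthetic-fixture generator emulates the real data regime — 5–15
  sparse time points per species on [0, 150] min, per-species scaling,
  additive Gaussian noise (sd = fraction × species amplitude) truncated at
  zero, one independent RNG stream per species.  It does not emulate blot
  saturation, loading-control drift, or between-source inconsistency, so
  passing recovery tests demonstrate correctness of the machinery, not
  robustness to real-blot artefacts.
* f1 weighting: the 1/(nm) prefactor is ambiguous when the number of points
  m varies by species; the default is per-species mean followed by the mean
  over species, with a `pooled` switch for the grand mean.
* The two-objective search is an in-package NSGA-II (fast nondominated
  sorting, crowding distance, binary tournament, SBX η=15, polynomial
  mutation η=20, elitist μ+λ selection) with an external nondominated
  archive; fully deterministic given a seed; defaults population 100,
  generations 100.  Each objective evaluation runs one 700-min simulation:
  the first 150 min supply the misfit, the event log the period; arrested or
  failed evaluations receive a large finite sentinel (1e6).
* Single-objective refits (parameter recovery against dense noiseless
  fixtures) use a derivative-free Nelder–Mead polish of f1 with a box
  penalty: the evolutionary search is the right tool for the conflicting
  two-objective landscape, but it is needlessly diffuse for recovering a
  handful of parameters whose misfit minimum is a point; the simplex descent
  reaches relative errors ~1e-3 in a few hundred evaluations where the
  genetic search stalls near 10–20 %.  No gradients are used anywhere.
* Sensitivity analysis perturbs whole parameter vectors by a common factor
  1 ± magnitude per draw and reports the mean relative change of each
  objective, excluding points whose baseline f2 is below 0.1 min (relative
  change is ill-conditioned near zero).

## Problem sizes used by the test-suite benchmarks

Settled-period benchmarks use 6000-min runs (≈40 cycles); the mutant panel
uses 2500-min runs; the QSSA comparison 2000 min; recovery tests refit 5
parameters from 12-point noiseless fixtures over three seeds.  These sizes
put every quoted number in its asymptotic regime (periods move by <0.01 min
with longer runs) while keeping a full run of the suite to about a minute.

## Known limitations

* No spatial structure: polar localisation, PopZ scaffolding and the
  swarmer/stalked compartments are outside scope; the cell is well-mixed.
* Division asymmetry is not modelled — the simulation follows a single
  cyclic lineage whose endpoint returns to its starting state, so systematic
  differences between daughter cells cannot be represented.
* The Z-ring is a fixed-rate clock, not a mechanistic constriction model;
  knockouts whose real phenotype acts through division timing (e.g. the
  40 %-longer doubling time of the *gcrA* knockout, simulated ~10 min
  longer) are underestimated by construction.
* DNA and chromosome-count bookkeeping variables do not feed back into the
  kinetics (no explicit gene-dosage multiplier beyond the (2 − h_Cori)
  factor on *dnaA*).
* The PleC forcing is an empirical fit, not a mechanistic PleC model; its
  rectification and per-division reset are modelling conventions (see
  above), and simulations far from a ~150-min cycle stretch the forcing
  assumption.
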