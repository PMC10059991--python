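# Methods

This note records the models, parameter choices and design decisions
behind `glucofed`, in the spirit of a statistical software methods
appendix.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Physiological preprocessing

Discrete dosing and meal events are converted into the continuous
covariates the forecasting grammar consumes.

**Insulin.**  Subcutaneous insulin passes through a linear
two-compartment chain into plasma:

    dS1/dt = U(t) − S1/t_max_I
    dS2/dt = (S1 − S2)/t_max_I
    dI/dt  = S2/(V_I·t_max_I) − k_e·I

with t_max_I = 55 min (time-to-maximum absorption), k_e = 0.138 min⁻¹
(fractional elimination), V_I = 0.12 L/kg (distribution volume).
Boluses are impulses into S1; the basal infusion is a piecewise-constant
U(t).  Because the system is linear and time-invariant, each 5-minute
step is propagated with the exact discrete update (matrix exponential of
the augmented system), so the solution has no step-size error;
superposition of overlapping doses holds to machine precision.  The
closed forms used as test oracles: steady state I_ss = U/(V_I·k_e) under
constant infusion, and agreement with adaptive ODE integration for a
single bolus.

V_I is per-kilogram and no body weight is modelled: signals are treated
as per-kg concentrations (weight = 1), since the evolved models only
need a consistent covariate scale.  An optional `weight` parameter on
`AbsorptionParams` restores absolute units.  Long-acting basal insulin
is routed through the same chain as boluses — a documented
simplification, as no separate basal absorption model is specified.

**Carbohydrate.**  A meal of D grams contributes the gut-absorption
kernel C(t) = D·A_g·(t−t₀)·e^(−(t−t₀)/t_max)/t_max², t_max = 40 min,
bioavailability A_g = 0.8.  The kernel peaks at lag t_max with value
D·A_g/(t_max·e) and integrates to D·A_g; overlapping meals add.  These
identities are the module's test oracles (the 5-minute left Riemann sum
recovers the mass within far less than 1%).

**Alignment and windowing.**  Events snap to the nearest CGM reading
(midpoint ties to the earlier reading).  A supervised sample anchors at
time t and carries k+1 = 13 past glucose values, h+1 = 7 insulin and
carbohydrate leads, k = 12 trend differences dG(t, t−jΔt) = G(t) −
G(t−jΔt) (current minus past), and the target G(t+hΔt) with its band.
Any window touching a missing glucose reading — history or target — is
discarded whole; missing data is never imputed, and no smoothing,
outlier removal or normalisation is applied.

## Glycemic bands and metrics

Glucose maps to seven right-open bands: <3.0, [3.0,3.9), [3.9,5.0),
[5.0,7.8), [7.8,10.0), [10.0,13.9), ≥13.9 mmol/L.  The three-way split
of the euglycemic range gives early "drifting towards hypo/hyper"
warnings.  mg/dL values convert by exactly 18 (the paired band bounds
force the factor).

The headline score is the class-frequency-weighted F1:
F1 = Σᵢ pᵢ·F1ᵢ with pᵢ the true-class frequency and F1ᵢ =
tpᵢ/(tpᵢ + 0.5(fpᵢ + fnᵢ)).  Weighted precision and recall use the same
weights; accuracy is trace/total.  Conventions: a class absent from both
truth and predictions contributes nothing (weight 0); a non-finite model
output is banded as a sentinel impossible class — a pure
misclassification that can never score a true positive.  Aggregation
margins (mean, standard deviation) across patients use the population
(n-denominator) standard deviation, the convention under which the
bundled benchmark margins reproduce exactly.

## The GE engine

Standard codon-based Grammatical Evolution: an individual is a
variable-length list of integers in [0, 100 000); the leftmost
derivation of the grammar consumes one codon per expansion and picks
production `codon mod m`.  The read head wraps at most twice; a
derivation still open after that — or deeper than 17 — is invalid and
scores fitness 0 (below every valid individual).  Initialisation is
position-independent grow with depth budgets drawn up to 10: at each
expansion a production is chosen uniformly among those whose minimal
completion depth fits the remaining budget, and a codon from the
matching residue class encodes the choice, guaranteeing valid
individuals.

Operators (defaults are the full-scale study settings; tests use scaled
populations): tournament selection of size 4 (ties to the earlier
population index), variable-length one-point crossover with probability
0.9 and per-parent cut points within the used codons, per-individual
int-flip mutation with probability 0.1 and one single-codon event
targeted at the used codons, elitism of 1.  Elitism makes the
best-so-far fitness monotone and testable; it can be disabled.
Genomes are capped at 500 codons.  "One mutation event" is read as a
per-individual event count (the 10% being the per-individual application
probability); the alternative per-codon reading is exposed through the
operator's parameters.

The exact production set of the published forecasting grammar is not
recoverable, so the bundled grammar is a documented reconstruction: the
top level is fully constrained to
`(<gexpr> - <iexpr> + <cexpr>) <op> <dgexpr>` with `<op> ::= + | - | *`,
and each block is arithmetic (parenthesised binary +, −, ·; plog; psqrt;
aq; digit-built decimal constants) over only its own variable set.  The
blocks are kept symmetric because nothing constrains their interiors
differently.

## Federation protocol

One slave per patient evolves on local training samples only.  The
master relays models at synchronous migration phases: after every
`migration_interval` completed generations each slave sends its best
individual (genome + rendered formula + sender-side fitness — never
data), receives the other slaves' bests, scores them on local training
data, and integrates them by worst-replacement (immigrants best-first,
each replacing the current worst member only if strictly better;
population size unchanged).  With g_max generations, exactly
⌊g_max/interval⌋ phases occur; when the interval divides g_max the last
exchange happens right after the final generation, before the final
best models are collected — so migration can improve the final local
bests too.  The non-federated baseline is the identical machinery with
migration disabled, sharing per-slave seeds, so comparisons are paired.

Transport is an in-process synchronous orchestrator stepping all slaves
in lockstep; the message contract (not the wire) is the implemented
artifact, and the privacy property — no sample-level data in any
message — is asserted structurally in tests.  Per-slave, per-run seeds
derive deterministically from the master seed via
`SeedSequence([master_seed, run, slave_index])`, so whole experiments
replay bit-identically.

After evolution, every final model is scored on every patient's test
samples (cross-evaluation); the *global model* is the row with the best
mean, ties to the lower patient id.  Its scores on held-out patients
that never participated measure generalization.

## Synthetic cohort generator

Real CGM data sets of this kind are access-restricted, so the package
ships a generator that emulates their structure rather than their
physiology.  Glucose follows a deliberately simple linear-response
update on the 5-minute grid,

    G(t+Δt) = clip(G(t) + α·C(t) − β·I(t) + γ·(G_b − G(t)) + ε, 2, 25)

driven by the same absorption signals the forecaster sees, with
ε ~ N(0, noise_sd²).  Defaults (one patient-week each, chosen once to
mimic the qualitative structure of real cohorts): basal glucose G_b
uniform in 5.5–9.5 mmol/L per patient; Poisson meal schedule of 3/day
with 30–120 g carbohydrate; boluses proportional to meal size
(0.05–0.18 mU/g on the per-kg signal scale, which keeps I(t) in roughly
[0, 10] mU/L) plus constant basal 0.002–0.005 mU/min; α ∈ [0.5, 0.9],
β ∈ [0.04, 0.08] (balanced so a carb-matched bolus roughly cancels its
meal; each patient is left somewhat over- or under-dosed, producing band
excursions), γ ∈ [0.01, 0.02]; noise_sd 0.15 mmol/L per step; 5% of
readings deleted.  Under these defaults glucose spans roughly
[2.6, 24.4] mmol/L and the two hypoglycemic bands jointly hold well
under 10% of samples — the imbalance that motivates weighted F1.

What the generator does *not* emulate: circadian structure, exercise,
sensor drift and compression artefacts, insulin-on-board interactions,
and real inter-patient physiology.  Tests passing on synthetic cohorts
therefore validate the machinery (preprocessing, evolution, federation,
statistics), not clinical performance on real patients.

## Statistics

The Quade test ranks algorithms within each subject (rank 1 = higher F1,
midranks on ties), weights subjects by the rank of their score range,
and forms F = (n−1)B/(A−B) with A = ΣS²ᵢⱼ, B = (1/n)ΣⱼSⱼ², F-distributed
with (k−1, (n−1)(k−1)) df.  Post-hoc z statistics compare weighted
average ranks with SE = √(k(k+1)(2n+1)(k−1)/(18n(n+1))), two-sided
normal p-values, and five adjustments (Bonferroni–Dunn, Holm, Hochberg,
Finner, Li); with k = 2 all five coincide with the raw p.  Decisions
reject at adjusted p < α (strict), α = 0.05 by default.  An all-tied
matrix (A = B) has an undefined statistic and is reported as an explicit
error.  No Quade implementation exists in scipy or statsmodels; this one
cross-checks against R's `stats::quade.test` (one frozen oracle value in
the tests) and against the published twelve-subject comparison, which it
reproduces to all printed decimals.

## Problem sizes in the test suite

The full-scale configuration (population 200, 500 generations,
migration every 100, 20 runs) is supported but the suite exercises
scaled versions: the federated-vs-independent replication uses 4
learning + 2 held-out synthetic patients of one week each, population
50, 100 generations, migration every 25, 20 runs per regime, across 5
master seeds derived from one base seed; the protocol-law check runs the
full 500 generations at population 8; ground-truth recovery uses
population 50 for 50 generations.  These sizes were chosen as the
smallest at which the compared quantities stabilise.

## Known limitations

* The OhioT1DM XML reader targets the simplified ts/value dialect with
  integer-minute timestamps; calendar-stamped exports need conversion.
* Bolus dose units in source data vary (mU vs U); the reader leaves
  values as-is and the unit question to the caller.
* The federation is synchronous and fault-free by design; encryption,
  authentication and asynchronous/fault-tolerant protocols are out of
  scope, as is any differential-privacy guarantee beyond "no raw data in
  messages".
* The evolved constants are built from single decimal digits; models
  needing finely tuned constants must compose them arithmetically.
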