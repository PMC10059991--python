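# glucofed

Federated grammatical evolution for interpretable, privacy-preserving
glucose-band forecasting from continuous glucose monitoring (CGM) data.

## The problem

People with type-1 diabetes manage their glucose with insulin dosing
guided by a CGM sensor sampling every Δt = 5 minutes.  Clinically, the
useful prediction is not the exact future value but the *glycemic band*
it will fall in 30 minutes from now — seven classes from "very low"
(< 3.0 mmol/L, immediate action) through three graded normal zones to
"very high" (≥ 13.9 mmol/L).  Two constraints make standard machine
learning awkward here:

* **privacy** — per-patient CGM records are sensitive and should never
  leave the patient's device/site;
* **interpretability** — clinicians want a formula they can read, not a
  weight matrix.

`glucofed` addresses both with a master/slave *federated evolutionary*
design: each patient ("slave") runs Grammatical Evolution (GE) on local
data only, and a master periodically relays each slave's best **model**
(never data) to the others, which adopt immigrant models that score well
locally.  The emergent models work well across patients — usable as
global models for patients who never took part in training.

## The model

Every candidate forecaster is an arithmetic expression generated by a
context-free grammar with the fixed four-block shape

```
Ĝ(t + hΔt) = ( Γ(G(t), …, G(t−kΔt)) − Θ(I(t), …, I(t+hΔt))
               + Ω(C(t), …, C(t+hΔt)) ) ◊ Φ(dG(t,t−Δt), …, dG(t,t−kΔt))
```

with ◊ ∈ {+, −, ·}, k = 12 past glucose values (60 min of history),
h = 6 leads (a 30-min horizon), and protected functions
plog(x) = log(1+|x|), psqrt(x) = √|x|, aq(x,y) = x/√(1+y²) keeping every
expression total.  The covariates are physiological signals, not raw
events: insulin doses pass through a linear two-compartment subcutaneous
absorption chain producing plasma insulin I(t), and meals through the
gut-absorption kernel C(t) = D·A_g·t·e^(−t/t_max)/t_max², both on the
CGM grid.  The predicted value is banded into the seven classes, and
fitness is the class-frequency-weighted F1 — the data are heavily
imbalanced (hypoglycemic samples are rare), so plain accuracy would
reward ignoring exactly the classes that matter most.

A statistics module implements the Quade test (blocks weighted by
within-subject score range) with Bonferroni–Dunn, Holm, Hochberg,
Finner and Li post-hoc adjustments, the protocol used to compare the
federated regime against independent per-patient evolution.

## Worked example

The synthetic cohort generator stands in for restricted clinical data;
it emulates the real structure (5-min grid, meals/boluses/basal, missing
readings, hypo-poor class imbalance).

```python
import glucofed as gf
from glucofed.estimators import GrammaticalEvolutionClassifier
from glucofed.windows import feature_columns, preprocess_series, train_test_split

cohort = gf.CohortConfig(n_patients=1, days=7.0, seed=0)
series = gf.assign_split(gf.simulate_patient(cohort, 0), 0.2)
samples = preprocess_series(series)          # k=12 past, h=6 ahead
train, test = train_test_split(samples)

clf = GrammaticalEvolutionClassifier(population_size=50, generations=50,
                                     random_state=1)
clf.fit(train[feature_columns()], train["target_class"])
print("evolved model:", clf.best_expression_)
print("train weighted F1: %.3f" % clf.best_fitness_)
print("test  weighted F1: %.3f" % clf.score(test[feature_columns()],
                                            test["target_class"]))
```

prints

```
evolved model: (g10-0+c1)-(plog(plog(plog((dg11-dg7))))-aq(dg11,(plog(plog(((dg11-dg7)-aq(dg11,(plog(plog((dg11+dg10)))-dg7)))))+dg11)))
train weighted F1: 0.888
test  weighted F1: 0.887
```

The evolved formula is directly readable: `g10` and `c1` are the glucose
level 50 minutes ago and the carbohydrate absorption 5 minutes ahead;
the `dg` block corrects by recent glucose trends.  A weighted F1 of
0.887 means the model assigns the correct 30-min-ahead glycemic band to
most test samples, with minority (hypo) classes weighted by their
frequency.

Federated experiments run through `glucofed.federation.run_experiment`
(or the `glucofed run` CLI): per-patient slaves evolve in lockstep,
exchange best models every `migration_interval` generations, and the
final best local models are cross-evaluated on every patient to select
the global model.  `glucofed.experiments.compare_modes` runs the
federated regime and the no-communication baseline with identical seeds
so the difference isolates the value of model migration.

## Layout

| module | contents |
| --- | --- |
| `glucofed.series`, `glucofed.cohort` | patient containers, OhioT1DM-style XML reader, internal CSV, synthetic cohort generator |
| `glucofed.absorption`, `glucofed.windows` | insulin/carb absorption signals, event alignment, sample windowing |
| `glucofed.bands` | glycemic banding, confusion matrices, weighted P/R/F1/accuracy |
| `glucofed.grammar`, `glucofed.evolve`, `glucofed.estimators` | BNF parsing, codon mapping, protected functions, the GE engine, sklearn-style classifier |
| `glucofed.federation`, `glucofed.experiments` | master/slave migration protocol, cross-evaluation, global-model selection, canned comparisons |
| `glucofed.stats`, `glucofed.benchmark` | Quade test + post hocs, bundled benchmark score tables |

See `docs/methods.md` for the modelling and design details.
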