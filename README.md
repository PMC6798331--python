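# bleedvalidate

Tools for validating ICD-10 discharge-diagnosis algorithms that identify
**major bleeding** in hospital claims data, for pharmacoepidemiologists who
need to know how far such algorithms can be trusted before using them to
measure bleeding incidence or anticoagulant safety.

Claims databases (such as the French PMSI hospital discharge database)
record one primary ICD-10 diagnosis per stay. A common phenotyping
algorithm maps that code to one of four exclusive categories —
intracranial hemorrhage (ICH), gastrointestinal (GI) bleeding, other
bleeding, or no bleeding event — from fixed code lists (I60, I61, I62,
S06.3–S06.6 for ICH; K25.0…K92.2 for GI; D62, R31, R04.x… for other). This
package implements that **index test** together with the machinery to
validate it:

* a **two-step reference standard**: an automated screen over
  emergency-ward codes and emergency therapies (transfusions, vitamin K,
  protamine sulfate, PCC, FEIBA), then criteria-based adjudication of
  major bleeding from structured chart features (systolic pressure
  < 90 mmHg or mean pressure < 65 mmHg or shock; uncontrollable bleeding;
  transfusion or hemostatic procedure; life-threatening location;
  ≥ 2 nasal packings; hematuria > 12 h despite bladder washing);
* **diagnostic accuracy statistics** from the typed contingency table
  (index category × reference status):

  Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
  LR⁺ = Se/(1−Sp), LR⁻ = (1−Se)/Sp,

  with exact two-sided **Clopper–Pearson** intervals for the proportions
  (lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k) beta quantiles)
  and log-normal intervals for the likelihood ratios;
* **discordance profiling** of false positives and false negatives
  (code frequencies, ICD-10 chapter mix, screen-pathway split);
* a **synthetic cohort generator** with known latent truth — a stochastic
  mode with configurable coding-error and screening rates for
  parameter-recovery experiments, and a deterministic mode that expands an
  explicit contingency specification (the packaged spec rebuilds a full
  16,012-stay validation cohort).

## Worked example

```sh
python examples/run_validation_study.py
```

runs the complete study on the packaged deterministic cohort and prints:

```
16012 stays; index test positive: 637

Index category x reference status (positive / negative):
  ICH      281 / 12
  GI       141 / 56
  OTHER     60 / 87
  NONE     254 / 15121
Sensitivity  65.5% (95% CI 61.9 to 68.9)  [k=482, n=736]
Specificity  99.0% (95% CI 98.8 to 99.1)  [k=15121, n=15276]
PPV          75.7% (95% CI 72.1 to 79.0)  [k=482, n=637]
NPV          98.3% (95% CI 98.1 to 98.5)  [k=15121, n=15375]
LR+          64.5
LR-          0.35
PPV ICH    96% (281/293)
PPV GI     72% (141/197)
PPV OTHER  41% (60/147)
```

Reading: of 736 reference-confirmed major bleeds, the discharge-code
algorithm caught 482 — a third of true major bleeds leave hospital under a
non-bleeding primary code, so the algorithm underestimates bleeding
incidence even though a positive call is highly informative (LR⁺ ≈ 65).
Accuracy is strongly differential across bleeding types: an ICH code is
almost always a confirmed major bleed (PPV 96%), an "other bleeding" code
usually is not (PPV 41%).

The other examples demonstrate the adjudication rules
(`adjudicate_charts.py`), error profiling (`profile_discordance.py`) and
parameter recovery on stochastic cohorts (`parameter_recovery.py`).

A thin CLI wraps the same functions:

```sh
bleedvalidate fixture --out stays.csv            # expand the packaged cohort
bleedvalidate run-all --cohort stays.csv --out results/
bleedvalidate simulate --seed 42 --out synthetic.csv
```

## Layout

* `src/bleedvalidate/codesets.py` — code normalization, category matching,
  codeset configs (`data/*.yaml` hold the replaceable defaults)
* `src/bleedvalidate/cohort.py` — stay-level data model, CSV round-trip
* `src/bleedvalidate/classify.py` — the index test and code-frequency tables
* `src/bleedvalidate/reference.py` — screen + adjudication reference standard
* `src/bleedvalidate/accuracy.py` — contingency tables, exact intervals, LRs
* `src/bleedvalidate/discordance.py` — false positive/negative profiling
* `src/bleedvalidate/synthetic.py` — generators (stochastic + deterministic)
* `src/bleedvalidate/report.py`, `cli.py` — one-shot runner, manifests, CLI

See `docs/methods.md` for the statistical and modelling details.
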