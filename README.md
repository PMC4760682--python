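# ddci — the Drug Derived Complexity Index

Tools for building and evaluating a **prescription-based comorbidity /
complexity score** over administrative claims.  The Drug Derived Complexity
Index (DDCI) stratifies a general population by mortality and
hospitalization risk using nothing but community pharmacy dispensing
records — no clinical data, no discharge diagnoses — which makes it usable
wherever only drug-claims data exist.  The intended audience is
pharmacoepidemiologists and health-services researchers working with
claims databases.

## The score

For each person, the year of dispensing records before an index date is
scanned against 19 drug-class rules (prescription patterns indicative of
chronic disease).  A typical rule reads *"at least 3 packages of drugs with
ATC codes C01B within 12 months"*; special rules cover a 2-package
antihyperglycemic threshold, 1-package neuro/psychiatric classes, ATC
exclusions (C07AB09; codeine and tramadol among opioids), and a 45-day
combination rule for hypertensive-heart-disease therapy.  Each class *k*
carries an integer weight

&nbsp;&nbsp;&nbsp;&nbsp;*w<sub>k</sub>* = round(*β<sub>k</sub>* / 0.3),&nbsp;&nbsp;halves away from zero,

where *β<sub>k</sub>* is the class coefficient from a multivariate Cox
proportional-hazards regression of overall mortality on the 19 exposure
flags (non-significant classes are excluded).  The raw score is the
algebraic sum of weights over a person's positive flags; with the published
weights it spans −3 … 36, and is folded into 12 risk classes (≤0 → class 0,
1–10 identity, ≥11 → class 11).  The package implements the rule engine,
the scorer, weight re-derivation from data, a Charlson Comorbidity Index
(CCI) comparator from ICD-9-CM discharge diagnoses, and the evaluation
battery: Kaplan–Meier curves by class, class-wise hazard ratios, Harrell's
survival C-index, continuous Net Reclassification Improvement (NRI), and
Poisson incidence-rate ratios for hospital readmissions.  A synthetic
claims-cohort generator reproduces the published exposure prevalences and
hazard structure so the whole pipeline is testable without real data.

## Worked example

Score a tiny hand-built cohort:

```python
from ddci import make_worked_fixture, detect_exposures_frame, score_cohort, compute_cci_frame

cohort, _ = make_worked_fixture()
flags = detect_exposures_frame(cohort.prescriptions, cohort.persons)
scores = score_cohort(flags)
scores["cci"] = compute_cci_frame(cohort.hospitalizations, cohort.persons)
print(scores.loc[["W03", "W08", "W11", "W12", "W16"]])
```

```
           raw_score  risk_class  cci
person_id
W03                2           2    0
W08                3           3    0
W11               -3           0    0
W12               13          11    0
W16                0           0    1
```

W03 meets the 2-package antihyperglycemic threshold (weight 2); W08
triggers the 45-day hypertensive-heart combination rule (weight 3); W11
takes only a statin and an immunosuppressant, scoring −3 — folded into the
lowest risk class; W12 combines opioids, anti-Parkinson and antineoplastic
therapy (6+4+3 = 13, top class); W16 has no qualifying prescriptions but a
baseline myocardial-infarction admission, so CCI = 1.

Run the full chain on a simulated cohort (derive weights on a random half,
evaluate the score on the other half):

```python
from ddci.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(out_dir="demo", n_persons=20_000, seed=42, split_seed=43))
print(res["comparison"].summary())
```

```
model comparison at horizon 7 y (n=10000)
  C reference: 0.738 (0.724-0.753)
  C augmented: 0.759 (0.745-0.774)
  NRI: 0.337 (0.276-0.398); events -0.2106, non-events 0.5476 (n=9700)
```

Adding the derived score to an age–sex Cox model raises the 7-year
mortality C-index from 0.738 to 0.759 and yields a clearly positive NRI —
the qualitative signature the index is designed for (most of the gain here
comes from correctly down-classifying non-events).  The same chain is
available from the shell:

```bash
ddci simulate --n 20000 --seed 42 --out cohort/
ddci exposures --cohort cohort/ --out flags.csv
ddci score --cohort cohort/ --exposures flags.csv --out scores.csv
ddci derive --cohort cohort/ --out weights.yaml
ddci run --n 20000 --seed 42 --out run/
```

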