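# news2l

Early-warning-score analysis for prehospital syncope: the **NEWS2**
vital-sign rubric, the lactate-augmented composite **NEWS2-L**, and the full
diagnostic-accuracy pipeline used to validate such scores against short-term
adverse outcomes.

Syncope — transient loss of consciousness from cerebral hypoperfusion — is a
common reason for emergency-medical-service calls, and most episodes are
benign. The clinical problem is spotting, at first contact and with nothing
but vital signs and a fingerstick lactate, the minority of patients at risk
of death within 48 hours, of needing advanced life support (intubation,
external pacing, vasoactive drugs), or of ICU admission. The package is
aimed at researchers evaluating early-warning scores on such cohorts, and at
anyone who needs auditable NEWS2 scoring or diagnostic-accuracy machinery.

## What it computes

**NEWS2** aggregates seven weighted observations (respiratory rate, SpO2,
supplemental oxygen, temperature, systolic blood pressure, heart rate,
consciousness) into a 0–20 total; totals above 5 (or any single parameter at
weight 3) trigger an urgent review, totals above 7 a critical-care review.
**NEWS2-L** adds the venous point-of-care lactate (mmol/L) to the total.

For a score *s* against a binary outcome, with test-positive defined as
*s* ≥ *c*:

- 2×2 panel at cut-off *c*: Se, Sp, PPV, NPV, LR+ = Se/(1−Sp),
  LR− = (1−Se)/Sp, diagnostic OR = (TP·TN)/(FP·FN), accuracy; Wilson
  intervals for proportions, Simel log intervals for LRs, Woolf for the OR.
- ROC curve and AUC (trapezoidal ≡ Mann–Whitney), DeLong variance and CI,
  paired DeLong comparison of two scores on the same patients, and the
  Youden-optimal cut-off maximising J = Se + Sp − 1.
- Reconstruction of published panels from group sizes and printed Se/Sp
  (round-half-up to integer counts), so every derived metric can be audited.
- A seeded synthetic cohort generator that emulates the published
  survivor/non-survivor structure (class-conditional median/IQR summaries,
  outcome rates) with NEWS2 always computed from the generated vitals.

## Worked example

```python
from news2l import VitalSigns, compute_news2, compute_news2_l

vitals = VitalSigns(respiratory_rate=22, spo2=93, on_supplemental_oxygen=False,
                    temperature=35.7, systolic_bp=105, heart_rate=82, gcs=14)
b = compute_news2(vitals)
c = compute_news2_l(b.total, lactate=3.4)
print(b.total, b.critical_review, c.news2_l)
```

prints `9 True 12.4`: the weights 2 (RR 21–24) + 2 (SpO2 92–93) + 1
(T 35.1–36) + 1 (SBP 101–110) + 3 (GCS < 15) sum to 9, which exceeds the
critical-review threshold of 7, and adding the lactate gives a composite of
12.4 — above the 9.5 cut-off associated with 48-hour mortality.

Auditing a published accuracy panel from its printed summaries:

```python
from news2l.pipeline import reproduce_table3
audit = reproduce_table3()
print(audit[audit.outcome == "death_48h"][["metric", "printed", "recomputed", "match"]])
```

reconstructs the mortality 2×2 table (tp=20, fp=64, fn=1, tn=276 from 21
non-survivors, 340 survivors, Se 95.2%, Sp 81.2%) and recomputes OR 86.25,
PPV 23.8%, NPV 99.6%, LR+ 5.06, LR− 0.06 and accuracy 82.0% — all matching
the printed panel. Across the three outcomes 23 of 24 metrics match; the
advanced-life-support odds ratio is internally inconsistent in the source
(its own counts give 18.86, not 18.26) and is flagged, not forced.

More examples live in `examples/` (one script per capability); the same
functionality is exposed on the command line:

```
news2l simulate --n 361 --seed 1 --out cohort.csv
news2l score --cohort cohort.csv --out scored.csv
news2l roc --cohort cohort.csv --outcome death_48h
news2l metrics --cohort cohort.csv --outcome death_48h --score news2_l --cutoff 9.5
news2l analyze --seed 1 --outdir results/
news2l table3
```

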