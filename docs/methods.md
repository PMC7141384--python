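# Methods

## Scoring model

NEWS2 is a deterministic band lookup: each of seven observations maps to a
weight in {0, 1, 2, 3} (supplemental oxygen: {0, 2}) and the total is their
sum, range 0–20. Inputs are compared at chart resolution — integers for
respiratory rate, SpO2, systolic pressure and heart rate; one decimal for
temperature, with half-up rounding applied first so the chart's apparent
gaps (e.g. 38.0 → 38.1) are unreachable. Consciousness accepts either a GCS
value or an AVPU category, exactly one of the two: GCS 15 ≡ Alert scores 0,
anything else scores 3. V, P and U are not distinguished because the rubric
weights them identically; "new confusion en route" is represented by the
caller supplying GCS < 15 or a non-Alert state — no temporal logic is
modelled. SpO2 Scale 2 is a per-patient clinical flag (diagnosed hypercapnic
respiratory insufficiency), never inferred from the saturation value.

NEWS2-L is the plain sum of the NEWS2 total and the lactate value in
mmol/L. It is a unitless composite; no weighting or rescaling of the
lactate is applied. Lactate outside the point-of-care device's measuring
range (0.8–21.7 mmol/L) is accepted with a flag rather than rejected: the
range is a property of one instrument, not of the score, and heavy-tailed
synthetic cohorts must remain scorable.

## Accuracy panel

Test-positive means score ≥ cut-off (ties positive). The reported Youden
cut-offs are midpoints between adjacent distinct observed scores, so no
observed value ever sits on a cut-off and the tie convention is moot on real
data. Confidence intervals: Wilson score for all proportions, Simel
log-normal for likelihood ratios, Woolf log for the odds ratio — the
standard diagnostic-accuracy choices when the source does not state a
method. A zero off-diagonal cell makes the OR degenerate; it is then
computed with the Haldane–Anscombe +0.5 correction on all cells and flagged,
keeping degenerate synthetic inputs finite and auditable.

Panel reconstruction inverts printed Se/Sp and group sizes to integer
counts with round-half-up (tp = ⌊se·n_pos + 0.5⌋, tn likewise). This
reproduces every printed mortality and ICU metric exactly and all
advanced-life-support metrics except the odds ratio, which is inconsistent
with its own row's prevalence/Se/Sp (implied counts give 18.86 vs the
printed 18.26). The mismatch is surfaced as a flag; no alternative rounding
was searched to force agreement.

The sample-size helper uses the normal-approximation formula
n = ⌈z² p(1−p)/d²⌉ for estimating a proportion p to half-width d, with
optional 1/(1−loss) enrolment inflation reported separately.

## ROC and DeLong machinery

The empirical ROC has one operating point per distinct score (ties grouped)
plus both corners; the trapezoidal area equals the Mann–Whitney pair
statistic identically, and the test suite holds them to 1e−12 against a
brute-force pair count. AUC variance uses DeLong structural components
(midrank placements); the paired two-score comparison subtracts twice the
component covariance. With perfect separation the variance estimate is
zero: the CI collapses onto the point estimate and the curve carries a
degeneracy flag rather than fabricating width. Direction is fixed — higher
score = more severe — with no automatic orientation detection. Youden ties
are broken toward the lower cut-off (higher sensitivity): in a triage
setting a missed true positive is the costlier error, consistent with the
emphasis on negative predictive value.

Monte-Carlo calibration in the test suite: under a paired null
(two independent standard-normal scores, 150 + 150 patients, 1,000
replicates) the test's rejection rate at α = 0.05 must lie in
[0.035, 0.065]; the 95% AUC interval's coverage of the true binormal AUC
Φ(1/√2) (500 per class, 2,000 replicates) must lie in [0.93, 0.97]. Both
run in a few seconds. For the Wilson intervals the exact coverage is
enumerable from the binomial pmf, so it is asserted noise-free and the
simulation is checked against the exact value within Monte-Carlo error;
the exact coverages at n = 50 are 0.962 (p = 0.05 or 0.95) and 0.935
(p = 0.5).

## Synthetic cohort generator

The generator emulates a two-class prehospital syncope cohort: 48-hour
survivors and non-survivors. Defaults are the published study conditions —
n = 361, mortality 5.8%, advanced life support in 76.2% of non-survivors
and 10.3% of survivors, ICU in 52.4% and 5.9%, admission in 100% and
34.1%, 45.4% women — and class-conditional median/IQR summaries for
respiratory rate, SpO2, temperature, systolic pressure, heart rate,
lactate and age.

**Quantile matching.** Publications report only median (q25–q75), so each
marginal is a distribution fitted to that triple:

- *shifted lognormal* (lactate, non-survivor respiratory rate): a location
  shift γ = (q25·q75 − m²)/(q25 + q75 − 2m) makes the triple exactly
  log-symmetric, giving a closed-form fit that reproduces all three
  quantiles to machine precision; left-skewed triples are fitted to their
  negation and reflected. A two-parameter lognormal cannot match
  non-log-symmetric quartiles (e.g. 1.8/2.6/3.6 forces q25 ≈ 1.84), which
  is why the three-parameter form is used.
- *truncated normal* (SpO2, temperature, systolic pressure, age): numeric
  least-squares quantile matching with hard physiological bounds; exact for
  symmetric triples, a small documented compromise for skewed ones (all
  default fits deviate < 4% on any quantile).
- *split normal* (heart rate, survivor respiratory rate): separate
  half-normal scales below and above the median, (m − q25)/z₀.₇₅ and
  (q75 − m)/z₀.₇₅ — exact for any skew, with light tails. Used where the
  published skew flips sign between classes and a lognormal tail would be
  pathological.

Samples are drawn by inverse transform, rounded to chart resolution and
clipped to hard bounds (SpO2 ≤ 100, rates and pressures floored at
physiological minima). Clipping moves only tail mass below the matched
quartiles, so the matched quantiles survive; the non-survivor heart-rate
floor acquires a small spike, a deliberate trade against lognormal tails
reaching zero.

GCS is discrete and its published survivor summary is degenerate
(15 [15–15]), so both classes use explicit categorical distributions whose
quartiles equal the published triples (survivors: 92% at 15; non-survivors:
median 14, q25 7, q75 15). ECG rhythm is sampled from the published
per-class frequencies and feeds nothing downstream. Supplemental-oxygen
rates are not published; 5% (survivors) and 45% (non-survivors) were chosen
once as clinically plausible EMS oxygen-use rates and documented here —
together with the GCS categoricals they are the only free parameters, and
the generator's first calibration run met every target with them.

**What is never sampled:** the NEWS2 total. It is always computed from the
generated vitals through the scoring module, so the published NEWS2
medians (3 survivors vs 11 non-survivors) act as an end-to-end calibration
check of the whole generative chain. At n = 10,000 the generated medians
are 3 and 10 with lactate medians on target, outcome prevalences within
Monte-Carlo error of 5.8/14.1/8.6%, and the mortality AUC ordering
NEWS2-L (≈0.97) > NEWS2 (≈0.93) > 0.5 matches the published ordering.

**Dependence structure.** Vitals are conditionally independent given class,
except SpO2 and respiratory rate, coupled by a Gaussian copula (ρ = −0.4,
configurable) so severe records look clinically coherent (tachypnoeic
patients tend to desaturate). The class-conditional margins already carry
all of the published structure; the copula is cosmetic.

## What the synthetic data do and do not show

Passing calibration shows the pipeline recovers the structure the generator
encodes; it does not validate the score on real patients. Known gaps from
real data: secondary outcomes (advanced life support, ICU) are conditioned
only on the survival class, not on severity within class, so their
synthetic AUCs (≈0.65) are structurally lower than published values
(0.84/0.81) — the published mortality AUC 0.948 and the ordering are
reachable, the secondary-outcome AUCs are qualitative references only, as
the underlying patient-level data are not deposited. Real vitals are also
integer-heaped and cross-correlated beyond the single copula pair, and real
cohorts contain incomplete observation sets, which the generator never
emits (the pipeline's exclusion path is tested with explicitly corrupted
tables).

## Numerical and design choices

- Round-half-up everywhere a published value was visibly rounded
  (reconstruction counts, display rounding: one decimal for percentages,
  two for ratios); banker's rounding would silently disagree with printed
  tables.
- Degenerate inputs fail loudly (missing vitals name the field; single-class
  outcomes are skipped with a logged warning while the run continues).
- Determinism contract: one `numpy` Generator seeded per run; fixed seed ⇒
  byte-identical cohort CSV and analysis reports.
- Problem sizes: calibration checks use 10,000-patient cohorts; DeLong
  calibration uses 1,000/2,000 replicates — sizes at which every
  Monte-Carlo band in the tests is several standard errors wide.
- Escalation thresholds are reported as flags only; no care-pathway logic
  (who performs the review) is modelled, and only first-contact
  observations are represented — no repeated measurements per patient.
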