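# Methods

## Surveillance model

The package implements two-stage (semi-automated) surveillance of deep and
organ/space surgical site infection after colorectal surgery. Stage one is
deterministic: five binary components are derived per surgery from
structured EHR event streams and combined by a Boolean rule into a
high/low probability class. Stage two (manual review of high-probability
records) is outside the software; its output — the reference-standard
deep-SSI label per surgery — is an *input* to the evaluation, never
recomputed. Free-text clinical notes are deliberately out of scope: a deep
SSI documented only in prose is invisible to structured-data components,
which is a known failure mode of this design, not of this implementation.

## Temporal conventions

All dates are calendar dates; within-day ordering is not modelled. The
surgery day is **day 1**, so `day_index = (event_date − surgery_date) + 1`.
This single anchor makes the two exclusion clauses coherent: "starting
after day 1" (antibiotics) means the run's first day is ≥ 2, and "prior to
day 1" (cultures) means strictly pre-surgery, with the surgery day itself
kept. The follow-up window is day 1..`fu_days` inclusive, default 45. The
reference-standard window (30 days) is carried in the config for
documentation but drives no computation.

Component choices where the published definitions leave room:

* **Length of stay** is counted from the surgery date to the index
  discharge (surveillance is anchored at surgery); a config switch
  (`los_from: admission`) counts from admission instead, since the source
  definitions do not say which was used. An open (undischarged) stay, or a
  discharge beyond the window, counts as prolonged.
* **Index admission** is the earliest episode whose interval contains the
  surgery date. If none exists, the component is evaluated on the
  readmission and mortality arms only and a warning is emitted.
* **Mortality** uses the discharge date of an episode flagged
  `died_in_hospital` as the death date; deaths after day 45 are ignored.
* **Reoperation** requires day ≥ 2, so the index procedure itself never
  counts; a genuine same-day return to theatre is not representable at day
  resolution (documented limitation).
* **Antibiotics** are evaluated on *distinct* administration days with ATC
  code prefix `J01`; doses and routes are ignored. The decision is
  existential: the component is true iff some ≥ 3 consecutive day-indices
  are all present, the first ≥ 2 and the last ≤ 45. A run straddling day
  45 is truncated at the edge before the length test. The existential
  reading (rather than testing the maximal run) keeps the component
  monotone — adding administrations can never turn it false — which a
  maximal-run reading violates as soon as a prophylactic day-1 dose
  touches a therapeutic course.
* **Relevant culture sites** are not enumerated in the source definitions;
  the default lookup (abdominal, pelvic, wound, drain, blood) ships as an
  editable set, and an explicit `relevant_site` column overrides it.
* **Radiology** filters on modality only (default `{CT}`); restriction to
  abdominal/pelvic CT is not modelled because the body region of an order
  is not reliably structured.

## Classification rules

A rule is `(required, optional, min_optional)`: high iff every required
component is present and at least `min_optional` optional ones are. The
exact branch structure of the source flow diagrams is not recoverable from
text, but this threshold form reproduces all reported classification
behaviour: the original rule (`required={microbiology}`, `min_optional=1`
of the rest) makes the culture necessary but not sufficient — cases with
2–3 components but no culture classify low — and the adapted rule
(`min_optional=2` of the four non-microbiology components) classifies
zero-component cases low and 2–3-component cases high. Users wanting the
source diagrams verbatim can encode them as custom YAML rules; the
`min_optional=2` adapted default is an inference, not a published
constant. Classification is purely Boolean; there are no scores and hence
no ties.

## Evaluation statistics

Positive = classified high; truth = deep SSI. Sensitivity, specificity,
PPV and NPV each get a Wilson score interval on their own denominator, with
the normal quantile at full double precision (1.959963…, not 1.96). A zero
denominator flags the metric *undefined* rather than reporting 0 or 1.
Workload reduction is (tn+fn)/N, the fraction of records never reviewed;
by construction it complements the review fraction exactly. Percentages
are rounded half-up to one decimal **only at render time**; JSON artifacts
carry full precision. (At these conventions 166/225 renders as 73.8;
published tables sometimes truncate such values downward by 0.1.)
Inter-annotator agreement is two-rater, two-category Cohen's κ with chance
agreement from the marginal label frequencies; κ is flagged undefined when
both raters are constant and identical (chance agreement 1).

## Synthetic cohort generator

The generator emulates the validation study's cohort so the entire
pipeline runs with no patient data. Defaults: n = 225 surgeries, deep-SSI
prevalence 0.182, and marginal component prevalences 0.387 (admissions),
0.178 (reoperation), 0.476 (radiology), 0.413 (antibiotics), 0.311
(microbiology). Components are sampled **conditionally independent given
SSI status**: only marginals are observable from published summaries, and
conditional independence is the minimal structure that exercises both
rules. The conditional table P(component | SSI) defaults to
(0.85, 0.55, 0.90, 0.90, 0.83); P(component | no SSI) is then derived
exactly as (m − p·a)/(1 − p) so implied marginals hit the targets. Under
these defaults the expected operating points are: original rule
sensitivity 0.829 / specificity 0.859, adapted sensitivity 0.983 /
specificity 0.712 — matching the direction (and closely the magnitude) of
the published comparison. Because every P(component | SSI) < 1, an
occasional zero-component deep SSI arises naturally, with no
special-casing. No attempt is made to reproduce the published confusion
table cell-exactly: the real joint dependence between components (e.g.
reoperation and culture are clinically correlated) is unobservable and is
left to user configuration.

Event realization plants, for each true indicator, events satisfying the
component predicate with dates drawn uniformly in their legal windows (no
seasonality), and for each false indicator only non-qualifying
distractors: day-1 prophylactic antibiotic runs, 1–2-day or gapped
post-operative courses, non-J01 anti-infectives, pre-operative cultures,
non-relevant-site cultures, non-CT imaging, pre-operative CTs,
other-department readmissions, wrong-specialty and post-window
reoperations. Distractor patterns are constructed so that even their union
cannot qualify (e.g. post-operative antibiotic distractors start at day
≥ 5, leaving a gap after a day-1..3 prophylaxis block); a per-surgery
check raises `RealizationError` if a configuration ever violates a planted
indicator. Consequently extraction recovers the planted indicator vector
exactly — the round-trip property the test suite verifies across seeds.

Randomness uses a single master seed with named substreams
(`SeedSequence(seed, spawn_key=(stream_id,))`), so adding a new event type
never perturbs existing draws. Covariates (age, sex, BMI, ASA class, wound
class, duration, stoma/primary/open/malignancy flags) are sampled from
simple parametric families matched to the emulated cohort's medians and
IQRs; they are passthrough realism only and feed no algorithm. The
simulated second annotator flips each reference label independently with
probability 0.05, emulating the ~95% observed double-review agreement.

### What passing tests show — and don't

The generator validates the *machinery*: window semantics, rule logic,
statistics, and end-to-end plumbing under realistic prevalences. It does
not validate transferability to real data: real component–SSI dependence
is not conditionally independent, culture practice varies by setting (the
very reason the culture-free rule can dominate), and free-text-only cases
are absent by construction. Performance numbers on synthetic cohorts are
calibration checks, not clinical evidence.

## Problem sizes

The test suite exercises: an exhaustive 32-profile truth table for every
rule; a 10⁴-case Wilson grid against a quadratic-root oracle (tolerance
1e-9); 1,000 random day-sets against a naive antibiotic-run scan; 10-seed
round-trips of full 225-surgery cohorts; a 10⁵-surgery marginal-recovery
check (3 SE); and a 500-cohort Monte-Carlo calibration run (mean
prevalence within 1 percentage point; marginals within 3 SE; adapted
sensitivity > original, original workload reduction > adapted). These
sizes were chosen to bound Monte-Carlo error well below the tolerances
they check.

## Known limitations

* Day resolution hides same-day reoperations and within-day ordering.
* Conditional independence understates clustering of components in true
  SSIs; tail behaviour (e.g. the exact count of zero-component SSIs per
  cohort) should not be read quantitatively.
* The `deaths.csv` join assigns a death to the episode containing the
  death date; deaths outside any episode are ignored (out-of-hospital
  deaths are not a component).
* No superficial-SSI components, no NLP, no FHIR/HL7 ingestion.
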