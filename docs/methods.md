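# Methods

## The problem

Identifying multiple sclerosis (MS) patients in routinely collected health
data is a phenotyping problem whose correct solution depends on *why* codes
are entered.  In a reimbursement-driven claims system a presumptive
diagnosis is coded at every test and visit, so true chronic disease leaves
dozens of codes while rule-out investigations leave a few; in a
general-practice EMR a confirmed diagnosis may be entered once and never
repeated, while disease-modifying treatments (DMTs) administered as
specialist infusions never appear at all.  This package implements a
claims algorithm that leans on repetition and complete drug capture, an
EMR algorithm that leans on supporting symptom and symptomatic-treatment
codes, and the shared machinery around them: exclusions, an incident-case
filter, exact 1:10 matching, index-date outcome ascertainment, 2×2
inference and simulated positive-predictive-value (PPV) validation.

## Date and interval conventions

Dates are ISO-8601 in files and integer day numbers in memory.  All
intervals are closed.  Fixed interval lengths are used so tests are exact:
1 year = 365 days, 6 months = 183 days, 1 week = 7 days, the
treated-condition proximity window is 90 days literal.  Age is completed
years computed with 365-day years; over a multi-decade record this drifts
by days from calendar age, which is immaterial here because matching
compares ages computed by the same rule on both sides.  Overlapping or
contiguous enrollment periods are merged at load.

## Classification rules and their edge cases

* All MS / demyelinating **count thresholds are evaluated on distinct
  dates**, in both dialects and in the exclusion rules.  The probable-tier
  wording is explicitly date-based; applying one convention everywhere
  keeps the rules consistent (two same-day EMR codes are one date and the
  patient is UNLIKELY without support).  DMT thresholds count prescription
  rows (sum of issues), contrasting with the date-based diagnosis counts.
* Where a record satisfies both the claims probable rule and the low-count
  possible rule (e.g. 10 diagnosis dates + 5 scripts), **PROBABLE wins**.
* EMR supporting codes count **regardless of their position relative to
  the first MS code**: no temporal window is imposed on support.
* A claims patient in the demyelinating-only possible tier has, by
  definition, no MS code; their **cohort entry date is the first
  demyelinating-disease code date**.  Every other tier anchors on the
  first MS code.
* Exclusions are checked in fixed priority order (ALS any time; alternate
  diagnosis with few MS codes — exactly one in the EMR dialect, fewer
  than five distinct dates in claims; stroke/TIA any time before or up to
  183 days after the first MS code, again with few codes).  Excluded
  patients keep their tier but never enter the cohort.
* Incident cases need one merged enrollment period covering the full
  closed year before the first MS code; enrollment starting exactly 365
  days before qualifies.

## Matching

The match key is (completed age at index, sex, index month and year,
geographic unit).  Controls must be MS-free at *any* time in the record
(no MS or demyelinating code ever — later-diagnosed patients would
otherwise contaminate the control arm), must satisfy the same 1-year
prior-enrollment rule as cases for look-back comparability, and adopt the
case's day-level index date.  Sampling is uniform without replacement,
sequential over cases in ascending index-date then patient-id order, and a
control serves at most one case.  Cases with no eligible control are
retained and flagged unmatched, so the MS cohort size is fixed before
matching.  When every case is fully matched, exact matching forces the
control arm's sex / age / geography / entry-month distributions to equal
the case arm's.

## Outcome rules

* Chronic comorbidities: ≥1 code ever before/on index (EMR) or ≥5 distinct
  dates (claims) — the claims threshold counts distinct dates, mirroring
  the classification convention, because claims repeat codes within an
  encounter.
* Per-symptom rows are descriptive and use a ≥1-code-ever rule in both
  dialects; symptom burden rows count patients with ≥1 / ≥2 distinct
  present symptoms.
* Treated depression / hypertension / type-II diabetes: a diagnosis code
  and a respective prescription within 90 days of each other (symmetric),
  both on/before index.
* Claims cancer: ≥5 codes within a 183-day span (implemented as a sliding
  window over sorted distinct dates), or ≥10 codes ever, or ≥1
  history-of-cancer / secondary code; EMR cancer: ≥1 cancer or history
  code.
* Acute infections: ≥1 code in the closed window [index − 365, index]
  (the index day itself counts).
* Hospitalized infections: an inpatient infection claim (claims) or an
  infection code with a hospitalization marker within ±7 days (EMR), in
  the 1-year window.
* Claims meningitis needs corroboration: ≥2 distinct-date codes plus a
  supporting symptom, symptomatic-treatment or antibiotic code in the
  window ("multiple" and the support set are parameters of the rule, which
  is qualitative in origin).
* Suicidal behaviour: ≥1 code ever; the overdose concept carries codes
  only in the EMR dialect, so it is invisible to the claims rule by
  construction of the codelist (a concept with no codes for a dialect is
  inactive there).
* Medications: prescription count in the 1-year window; anticonvulsants
  are attributed to epilepsy treatment when *any* epilepsy diagnosis
  exists on/before index (a single code suffices for attribution in both
  dialects), otherwise to MS-symptom treatment.
* BMI bands are half-open ([18.5, 25), [25, 30), [30, ∞)); the most
  recent observation on/before index wins; missing → unknown.

Events strictly after a patient's index date never influence any outcome.

## Statistics

Pearson chi-square with 1 df and no continuity correction (the default of
the commercial statistical suite such studies are analysed with), replaced
by a two-sided Fisher exact test when the minimum *observed* cell is below
5 — a literal reading of "cell sizes", not expected counts.  The Fisher
two-sided p sums table probabilities no larger than the observed table's.
No multiplicity adjustment is applied, matching descriptive-study
practice.  Percentages round half-away-from-zero to one decimal, so a
printed percentage always recomputes from its printed count and cohort N.
Medians among medication users take the lower median on even counts so
every reported median is an attainable integer.

## The synthetic-data generator

The generator emulates the *coding process*, not disease biology.  Its
packaged defaults transcribe the MS-cohort columns of a published
two-country MS cohort description (a US military claims population and a
UK primary-care EMR population): female share 71.4% / 70.2%, age-band
weights, entry-year weights, record-length distribution, and per-concept
symptom / comorbidity / infection / medication prevalences for the MS and
non-MS strata.  Design choices a maintainer should know:

* **Anchored placement.**  Every patient has a simulation anchor date (for
  true cases, the first MS code).  Chronic-condition codes are placed
  uniformly between enrollment start and the anchor, acute infections and
  medications inside the 365-day pre-anchor window — i.e., exactly the
  windows the ascertainment rules inspect, because the source material
  reports window-level prevalence, not event timing.  The anchor is
  recorded in the ground-truth table (never in the record files) so
  parameter recovery can be verified for the non-MS stratum too.
* **Exact-quota sex assignment.**  The per-stratum female fraction is
  assigned by shuffled quota rather than i.i.d. draws, so the packaged
  71.4% is realized exactly in expectation-free fashion; with the default
  2% MS fraction at n = 50,000 (1000 cases) the quota is exactly
  representable.
* **Claims coding.**  A probable-stratum case draws 10 + NB(mean 35,
  dispersion 1.6) distinct diagnosis dates and 5 + NB(mean 25, 1.6) DMT
  scripts — heavy right skew with a median near the mid-40s diagnoses and
  ~30 scripts.  The configured tier mix (82.5% probable / 0.4%
  demyelinating-only / 17.1% low-count) reproduces the observed tier
  shares; a low-count draw occasionally crosses the probable boundary, so
  the realized probable share sits slightly above the configured weight.
* **EMR coding.**  MS-code counts are drawn from {1, 2, 3+} weights
  (default 0.33 / 0.33 / 0.34, putting 66% of cases at one or two codes);
  DMT capture is 25% versus 100% in claims.
* **Matched pool.**  Each true case is accompanied by 20 MS-free patients
  sharing sex, geography and birth date and enrolled over the case's index
  window, so 1:10 exact matching is feasible by construction.  The depth
  of 20 leaves headroom for match-key collisions between cases (two cases
  with the same key, or a case whose index aligns with another case's
  pool) and for confounder-injected pool members.  Remaining patients get
  independent demographics.
* **Confounder injection.**  Small configurable fractions of both strata
  receive ALS, stroke, TIA or alternate-diagnosis codes; an injected
  non-MS patient also receives a single spurious (rule-out style) MS code.
  Stroke/TIA codes land uniformly within ±2 years of the anchor, so some
  injected non-MS patients escape the 6-month exclusion window and
  populate the UNLIKELY and supported-possible tiers as genuine false
  positives — which is what makes the simulated PPV validation
  non-trivial (probable stays at 100% because a false positive can never
  accrue two distinct MS-code dates).
* **Determinism.**  One master seed lays out the population skeleton; each
  patient's events come from a substream keyed by a CRC-32 hash of the
  patient id, so content is independent of insertion order and two runs
  with the same config are byte-identical.

### What the generator does *not* emulate

No disease progression, health-care-seeking correlation between outcomes
(outcomes are independent given stratum), regional prevalence variation,
post-index treatment dynamics, mortality, or code-vocabulary realism (the
packaged codelist's code strings are illustrative stand-ins).  Passing
tests therefore demonstrate that the pipeline implements its rules
faithfully and recovers known parameters — not that the algorithms would
achieve any particular sensitivity or PPV on real claims or EMR data.

### Known interactions

The hospitalized-infection mechanism adds one site-level infection code
for a uniformly chosen site, slightly inflating per-site acute prevalence
(bounded by the hospitalized prevalence divided by the number of sites);
the treated-pair mechanism reuses an in-window prescription when the
medication-class flag fired, or places the pair's prescription *older*
than the 1-year window otherwise, so configured medication-use rates stay
exact; the claims meningitis mechanism adds one antibiotic prescription.
Parameter-recovery checks account for the first of these analytically and
the others are below measurement noise at the tested sizes.

## Problem sizes used in the test suite

Unit and property tests run on hand-built records and populations of a few
hundred to a few thousand patients.  The study-level checks use the
packaged configurations at n = 50,000 (one claims and one EMR population,
fixed seed) and twenty independent 5,000-patient EMR populations for the
PPV-ordering check — sizes at which binomial 99.7% recovery bounds are
tight enough to be meaningful while the whole suite stays fast.

## Limitations

The two algorithms are faithful implementations of fixed rule sets; the
package does not learn or tune thresholds.  The matcher is greedy and
sequential (no optimal assignment), which mirrors standard epidemiological
practice but can under-match late cases in thin strata.  Fisher p-values
use exact enumeration via the hypergeometric distribution and are two
sided by the minimum-likelihood criterion; one-sided variants are not
exposed.  The UNLIKELY tier exists only in the EMR dialect, as defined.
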