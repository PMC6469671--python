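# msphen

Rule-based multiple sclerosis (MS) phenotyping, matched-cohort construction
and comorbidity ascertainment for coded longitudinal health records, in two
database *dialects*:

* **claims** (`CLAIMS_DOD`) — reimbursement-driven records where a diagnosis
  code repeats at every billable encounter (including screening and rule-out
  visits) and drug capture is complete;
* **EMR** (`EMR_CPRD`) — clinician-maintained primary-care records where a
  confirmed chronic diagnosis may be coded only once or twice and
  specialty-administered drugs are mostly absent.

The same clinical question — *who has MS, when were they first diagnosed,
and what did their health look like at that moment?* — needs different
algorithms in the two systems, and this package implements both, plus
everything needed to evaluate them end to end without access to any real
(proprietary) data.

## What it does

1. **Synthetic populations** (`msphen.synth`) — a seeded generator emulates
   each dialect's coding process with known per-patient ground truth:
   negative-binomial code repetition and complete disease-modifying
   treatment (DMT) capture in claims; one-or-two-code chronic coding (66%
   of cases by default) and rare DMT capture in the EMR dialect; symptom,
   comorbidity, infection and medication events sprinkled at configurable
   prevalences per stratum; confounder-injection scenarios (ALS, stroke,
   TIA, alternate diagnosis) that exercise every exclusion branch.
2. **Case classification** (`msphen.classify`) — tiered algorithms:
   * claims: gate (≥1 MS/demyelinating code AND ≥1 DMT prescription), then
     PROBABLE (≥10 distinct MS-or-demyelinating dates + ≥5 DMT scripts, or
     ≥5 distinct MS dates + ≥10 scripts) or a possible tier;
   * EMR: PROBABLE (≥2 distinct MS dates + supporting symptom/treatment
     codes), possible tiers, and UNLIKELY (one code, no support — reported,
     never enrolled);
   * shared exclusions (ALS ever; alternate diagnosis or stroke/TIA near
     the first MS code when few MS codes exist) and an incident filter
     (≥1 year of enrollment before the first MS code).
3. **Exact matching** (`msphen.matching`) — up to 10 MS-free controls per
   case on exact age-at-entry, sex, entry month/year and geography; a
   control serves at most one case; controls inherit the case's index date.
4. **Outcome ascertainment** (`msphen.outcomes`) — a declarative rule
   engine evaluated at the index date: chronic conditions (≥1 code EMR /
   ≥5 distinct dates claims), treated depression/hypertension/diabetes
   (diagnosis and prescription within 90 days of each other),
   dialect-specific cancer and hospitalized-infection rules, 1-year acute
   infection windows, suicidal behaviour, concomitant medication counts and
   anticonvulsant attribution (epilepsy vs MS-symptom treatment).
5. **Comparison tables** (`msphen.stats`, `msphen.tables`) — MS vs non-MS
   2×2 tables per outcome, Pearson chi-square (1 df, no continuity
   correction) switching to a two-sided Fisher exact test when any observed
   cell is below 5, percentages rounded half-up to one decimal,
   small-cell "NR" suppression, medians among medication users.
6. **PPV validation** (`msphen.ppv`) — stratified adjudication samples
   against ground truth and positive predictive value overall and per
   certainty tier.

## Worked example

Run the whole study pipeline on a 20,000-patient claims-style population:

```bash
msphen run --dialect dod --n 20000 --seed 11 --out demo/
```

which prints the per-stage manifest (abridged):

```json
{
  "classify": {
    "cohort_n": 399,
    "tiers": {"NON_CASE": 19600, "POSSIBLE_DEMYELINATING_ONLY": 3,
              "POSSIBLE_LOW_COUNT": 58, "PROBABLE": 339}
  },
  "match": {"cases": 399, "controls": 3990, "fully_matched": 399},
  "validate": {"overall_ppv": 1.0}
}
```

399 of the 400 simulated true-MS patients enter the incident cohort (one is
removed by the exclusion rules), 85% of cases are PROBABLE, and every case
finds its 10 exactly matched controls.  The comorbidity table
(`demo/table4.csv`) then reads, per row, `count (percent)` with a `*`
marking p < 0.01 and `NR` suppressing small cells:

```text
row,ms,nonms,test,p_value
treated_depression,82 (20.6)*,614 (15.4),chi_square,0.007105045030174792
epilepsy,NR,16 (0.4),fisher_exact,0.6760034999247683
```

i.e. treated depression is ascertained in 20.6% of MS patients at diagnosis
versus 15.4% of matched controls — the kind of contrast the pipeline is
built to surface — while the epilepsy cell is too small to report.  The
simulated questionnaire validation (`demo/ppv.csv`) reports PPV per
certainty tier with Wilson intervals.

Every stage is also available separately (`msphen simulate|classify|match|
ascertain|compare|validate`) and as plain library calls
(`generate_population`, `build_ms_cohort`, `match_cohort`,
`ascertain_cohort`, `build_tables`, `compute_ppv`).

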