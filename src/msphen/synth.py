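"""Seeded generator of dialect-faithful synthetic populations.

No real claims or EMR data can be shipped, so every downstream stage is
exercised on synthetic populations with known ground truth.  The generator
emulates the *coding process* of each dialect, not disease biology:

* In the claims dialect, a true MS patient accumulates many MS diagnosis
  codes on distinct dates (heavy right-skewed negative-binomial repetition,
  because a code is entered at every billable encounter) and their
  disease-modifying treatment (DMT) prescriptions are fully captured.
* In the EMR dialect, a true MS patient receives one, two, or a few MS
  codes (configurable weights; the packaged default puts 66% of cases at
  one or two codes) and DMT capture is rare, while supporting symptom and
  symptomatic-treatment codes are common.

Symptom, comorbidity, infection and medication events are sprinkled at
configurable per-concept prevalences, separately for the MS and non-MS
strata, inside the windows the ascertainment rules inspect (chronic
conditions any time before the reference date, acute infections and
medications within the year before).  Confounder-injection scenarios (ALS,
stroke, TIA, alternate diagnosis — optionally with a single spurious MS
code for non-MS patients) exercise every exclusion branch and create the
imperfect lower certainty tiers a validation study adjudicates.

So that exact 1:10 matching is achievable, the generator builds a matched
pool: each true MS patient is accompanied by ``controls_per_case_pool``
MS-free patients sharing sex, geography and birth date, enrolled over the
case's index window (the default of 20 leaves headroom for occasional
match-key collisions between cases and for confounder-injected pool
members).  Remaining patients get independent demographics.

Determinism: one master seed orders the population skeleton; each
patient's events come from a substream keyed by a stable hash of the
patient id, so generated content is independent of insertion order.
"""

from __future__ import annotations

import datetime as _dt
import zlib
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .records import (
    DAYS_PER_YEAR,
    Bundle,
    CodedEvent,
    CovariateObs,
    Dialect,
    EnrollmentPeriod,
    Patient,
    PatientRecord,
    Prescription,
    format_day,
)

__all__ = ["Strat", "NegBinModel", "GeneratorConfig", "GroundTruth",
           "generate_population", "default_configs", "write_ground_truth"]

Prob = Field(ge=0.0, le=1.0)


class Strat(BaseModel):
    """A probability pair: MS stratum / non-MS stratum."""

    ms: float = Prob
    nonms: float = Prob

    def for_stratum(self, true_ms: bool) -> float:
        return self.ms if true_ms else self.nonms


class NegBinModel(BaseModel):
    """Negative-binomial count model (mean / dispersion parameterization)."""

    mean: float = Field(gt=0)
    dispersion: float = Field(gt=0)

    def sample(self, rng: np.random.Generator) -> int:
        r = self.dispersion
        p = r / (r + self.mean)
        return int(rng.negative_binomial(r, p))


def _norm(weights: dict[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    return {k: v / total for k, v in weights.items()}


def _check_weights(name: str, weights: dict[str, float]) -> None:
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name}: weights must sum to 1 (got {sum(weights.values())})")
    if any(v < 0 for v in weights.values()):
        raise ValueError(f"{name}: negative weight")


class GeneratorConfig(BaseModel):
    """Full parameterization of one synthetic population."""

    n_patients: int = Field(gt=0)
    ms_fraction: float = Prob
    female_fraction_ms: float = Prob
    female_fraction_nonms: float = Prob
    age_band_weights: dict[str, float]
    age_band_ranges: dict[str, tuple[int, int]] = {
        "<40": (7, 39),
        "40-59": (40, 59),
        "60+": (60, 85),
    }
    entry_year_weights: dict[str, float]  # "YYYY-YYYY" bins
    n_geography_units: int = Field(gt=0)
    controls_per_case_pool: int = Field(default=20, ge=0)
    pre_entry_years_weights: dict[str, float] = {
        "1-2": 0.25,
        "3-5": 0.30,
        "6-9": 0.25,
        "10+": 0.20,
    }
    # claims-dialect MS coding process
    dod_tier_mix: dict[str, float] = {
        "probable": 0.825,
        "demyelinating_only": 0.004,
        "low_count": 0.171,
    }
    claims_repeat_model: NegBinModel = NegBinModel(mean=35.0, dispersion=1.6)
    dmt_rx_model: NegBinModel = NegBinModel(mean=25.0, dispersion=1.6)
    # EMR-dialect MS coding process
    emr_ms_code_count_weights: dict[str, float] = {"1": 0.33, "2": 0.33, "3+": 0.34}
    emr_extra_ms_codes_mean: float = Field(default=2.0, ge=0)
    dmt_capture_prob: float = Prob
    symptomatic_treatment_prob: Strat = Strat(ms=0.30, nonms=0.05)
    # outcome prevalences, keyed by concept name
    symptom_prevalences: dict[str, Strat] = {}
    treated_pair_prevalences: dict[str, Strat] = {}
    comorbidity_prevalences: dict[str, Strat] = {}
    cancer_prevalence: Strat = Strat(ms=0.0, nonms=0.0)
    cancer_history_frac: float = Field(default=0.3, ge=0, le=1)
    infection_prevalences: dict[str, Strat] = {}
    hospitalized_infection_prevalence: Strat = Strat(ms=0.0, nonms=0.0)
    suicidal_prevalence: Strat = Strat(ms=0.0, nonms=0.0)
    medication_use_probs: dict[str, Strat] = {}
    medication_mean_extra_rx: dict[str, float] = {}
    smoking_weights: dict[str, dict[str, float]] = {
        "ms": {"unknown": 1.0},
        "nonms": {"unknown": 1.0},
    }
    bmi_weights: dict[str, dict[str, float]] = {
        "ms": {"unknown": 1.0},
        "nonms": {"unknown": 1.0},
    }
    exclusion_scenario_fracs: dict[str, float] = {
        "als": 0.0005,
        "stroke": 0.001,
        "tia": 0.001,
        "alternate": 0.002,
    }
    seed: int = 0

    @model_validator(mode="after")
    def _validate_weights(self) -> "GeneratorConfig":
        _check_weights("age_band_weights", self.age_band_weights)
        _check_weights("entry_year_weights", self.entry_year_weights)
        _check_weights("pre_entry_years_weights", self.pre_entry_years_weights)
        _check_weights("dod_tier_mix", self.dod_tier_mix)
        _check_weights("emr_ms_code_count_weights", self.emr_ms_code_count_weights)
        for stratum, w in {**self.smoking_weights, **self.bmi_weights}.items():
            _check_weights(f"covariate weights [{stratum}]", w)
        if sum(self.exclusion_scenario_fracs.values()) > 1.0 + 1e-9:
            raise ValueError("exclusion_scenario_fracs sum exceeds 1")
        for name, strat_map in (
            ("symptom_prevalences", self.symptom_prevalences),
            ("treated_pair_prevalences", self.treated_pair_prevalences),
            ("comorbidity_prevalences", self.comorbidity_prevalences),
            ("infection_prevalences", self.infection_prevalences),
            ("medication_use_probs", self.medication_use_probs),
        ):
            for key, strat in strat_map.items():
                if not (0 <= strat.ms <= 1 and 0 <= strat.nonms <= 1):
                    raise ValueError(f"{name}[{key}]: probability out of [0, 1]")
        if set(self.age_band_weights) != set(self.age_band_ranges):
            raise ValueError("age band weights/ranges keys differ")
        return self


class GroundTruth(BaseModel):
    """Per-patient simulation truth; never written into the record files."""

    patient_id: str
    true_ms: bool
    true_onset_day: Optional[int] = None
    injected_confounder: str = "none"  # none|als|stroke|tia|alternate
    anchor_day: int = 0  # simulation reference date (first-MS date for cases)

    @model_validator(mode="after")
    def _onset_iff_ms(self) -> "GroundTruth":
        if self.true_ms != (self.true_onset_day is not None):
            raise ValueError("true_onset_day present iff true_ms")
        return self


_PAIR_CONCEPTS = {
    "depression": ("depression", "antidepressant"),
    "hypertension": ("hypertension", "antihypertensive"),
    "diabetes": ("diabetes_t2", "oral_hypoglycemic"),
}
_INFECTION_SITES_NO_MENINGITIS = (
    "urinary_infection",
    "skin_infection",
    "respiratory_infection",
    "pneumonia_influenza",
    "eye_ear_infection",
    "viral_infection",
    "fungal_infection",
)
_BMI_VALUE_RANGES = {
    "<18.5": (15.0, 18.4),
    "18.5-25": (18.5, 24.9),
    "25-30": (25.0, 29.9),
    "30+": (30.0, 45.0),
}
_DMT_CONCEPTS = ("interferon_beta", "glatiramer", "natalizumab", "fingolimod")


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    key = zlib.crc32(patient_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _uniform_day(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _distinct_days(rng: np.random.Generator, lo: int, hi: int, k: int) -> list[int]:
    span = hi - lo + 1
    if k >= span:
        return list(range(lo, hi + 1))
    return sorted(int(lo + d) for d in rng.choice(span, size=k, replace=False))


def _entry_day(rng: np.random.Generator, entry_year_weights) -> int:
    bin_key = _choice(rng, entry_year_weights)
    y0, y1 = (int(t) for t in bin_key.split("-"))
    year = int(rng.integers(y0, y1 + 1))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    return _dt.date(year, month, day).toordinal()


def _pre_entry_days(rng: np.random.Generator, weights) -> int:
    band = _choice(rng, weights)
    bounds = {"1-2": (365, 730), "3-5": (3 * 365, 5 * 365),
              "6-9": (6 * 365, 9 * 365), "10+": (10 * 365, 14 * 365)}[band]
    return _uniform_day(rng, *bounds)


def _quota_vector(rng: np.random.Generator, n: int, frac: float, a: str, b: str):
    n_a = int(round(n * frac))
    vec = np.array([a] * n_a + [b] * (n - n_a), dtype=object)
    rng.shuffle(vec)
    return vec


class _PatientBuilder:
    def __init__(self, pid, sex, birth, geography, dialect):
        self.patient = Patient(pid, sex, birth, geography, dialect)
        self.periods: list[EnrollmentPeriod] = []
        self.events: list[CodedEvent] = []
        self.rx: list[Prescription] = []
        self.covs: list[CovariateObs] = []
        self._start = 0
        self._end = 0

    def enroll(self, start: int, end: int) -> None:
        self._start, self._end = start, end

    def ev(self, day: int, concept: str, setting: str = "outpatient") -> None:
        self.events.append(CodedEvent(int(day), concept, setting))
        if day > self._end:
            self._end = int(day)

    def add_rx(self, day: int, concept: str) -> None:
        self.rx.append(Prescription(int(day), concept, 1))
        if day > self._end:
            self._end = int(day)

    def build(self) -> PatientRecord:
        return PatientRecord(
            self.patient,
            [EnrollmentPeriod(self._start, self._end)],
            self.events,
            self.rx,
            self.covs,
        )


def _place_common_events(
    b: _PatientBuilder,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    true_ms: bool,
    start: int,
    anchor: int,
    dialect: Dialect,
) -> None:
    """Symptoms, comorbidities, infections, medications and covariates."""
    is_dod = dialect == Dialect.CLAIMS_DOD
    win_lo = anchor - DAYS_PER_YEAR  # acute / medication window

    for concept, strat in cfg.symptom_prevalences.items():
        if rng.random() < strat.for_stratum(true_ms):
            k = 1 + (int(rng.poisson(0.7)) if is_dod else 0)
            for d in _distinct_days(rng, start, anchor, k):
                b.ev(d, concept)
    if rng.random() < cfg.symptomatic_treatment_prob.for_stratum(true_ms):
        concept = "oxybutynin" if rng.random() < 0.5 else "modafinil"
        b.add_rx(_uniform_day(rng, start, anchor), concept)

    for concept, strat in cfg.comorbidity_prevalences.items():
        if rng.random() < strat.for_stratum(true_ms):
            if is_dod:
                k = 5 + min(int(rng.poisson(3)), 30)
            else:
                k = 1 + (1 if rng.random() < 0.3 else 0)
            for d in _distinct_days(rng, start, anchor, k):
                b.ev(d, concept)

    # concomitant medications first, so treated pairs can reuse an
    # in-window prescription without distorting configured use rates
    med_days: dict[str, list[int]] = {}
    for concept, strat in cfg.medication_use_probs.items():
        if rng.random() < strat.for_stratum(true_ms):
            lam = max(cfg.medication_mean_extra_rx.get(concept, 1.0), 0.0)
            k = 1 + int(rng.poisson(lam))
            days = [_uniform_day(rng, win_lo, anchor) for _ in range(k)]
            for d in days:
                b.add_rx(d, concept)
            med_days[concept] = days

    for key, strat in cfg.treated_pair_prevalences.items():
        if rng.random() >= strat.for_stratum(true_ms):
            continue
        dx_concept, rx_concept = _PAIR_CONCEPTS[key]
        if rx_concept in med_days:
            r = int(rng.choice(med_days[rx_concept]))
        else:
            # historical treated episode: prescription older than the
            # 1-year medication window so configured use rates stay exact
            r = _uniform_day(rng, start, max(anchor - DAYS_PER_YEAR - 1, start))
            b.add_rx(r, rx_concept)
        dx = int(np.clip(r + rng.integers(-90, 91), start, anchor))
        b.ev(dx, dx_concept)

    if rng.random() < cfg.cancer_prevalence.for_stratum(true_ms):
        if not is_dod:
            concept = (
                "cancer_history"
                if rng.random() < cfg.cancer_history_frac
                else "cancer"
            )
            b.ev(_uniform_day(rng, start, anchor), concept)
        elif rng.random() < cfg.cancer_history_frac:
            b.ev(_uniform_day(rng, start, anchor), "cancer_history")
        else:
            s0 = _uniform_day(rng, start, max(anchor - 150, start))
            k = 5 + int(rng.poisson(2))
            for d in _distinct_days(rng, s0, min(s0 + 150, anchor), k):
                b.ev(d, "cancer")

    for concept, strat in cfg.infection_prevalences.items():
        if rng.random() < strat.for_stratum(true_ms):
            if concept == "meningitis" and is_dod:
                for d in _distinct_days(rng, win_lo, anchor, 2):
                    b.ev(d, "meningitis")
                b.add_rx(_uniform_day(rng, win_lo, anchor), "antibiotic")
            else:
                k = 1 + (int(rng.poisson(0.5)) if is_dod else 0)
                for _ in range(k):
                    b.ev(_uniform_day(rng, win_lo, anchor), concept)

    if rng.random() < cfg.hospitalized_infection_prevalence.for_stratum(true_ms):
        site = _INFECTION_SITES_NO_MENINGITIS[
            int(rng.integers(len(_INFECTION_SITES_NO_MENINGITIS)))
        ]
        d = _uniform_day(rng, win_lo, anchor)
        if is_dod:
            b.ev(d, site, setting="inpatient")
        else:
            b.ev(d, site)
            marker = int(np.clip(d + rng.integers(-7, 8), win_lo, anchor))
            b.ev(marker, "hospital_admission")

    if rng.random() < cfg.suicidal_prevalence.for_stratum(true_ms):
        concept = "self_harm"
        if not is_dod and rng.random() < 0.3:
            concept = "overdose"
        b.ev(_uniform_day(rng, start, anchor), concept)

    stratum = "ms" if true_ms else "nonms"
    smoking = _choice(rng, cfg.smoking_weights[stratum])
    if smoking != "unknown":
        b.covs.append(
            CovariateObs(_uniform_day(rng, start, anchor), "smoking", smoking)
        )
    band = _choice(rng, cfg.bmi_weights[stratum])
    if band != "unknown":
        lo, hi = _BMI_VALUE_RANGES[band]
        value = round(float(lo + rng.random() * (hi - lo)), 1)
        b.covs.append(CovariateObs(_uniform_day(rng, start, anchor), "bmi", value))


def _place_ms_coding(
    b: _PatientBuilder,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    anchor: int,
    dialect: Dialect,
) -> None:
    """The dialect-specific MS diagnosis / DMT coding process for a true case."""
    if dialect == Dialect.CLAIMS_DOD:
        tier = _choice(rng, cfg.dod_tier_mix)
        if tier == "probable":
            n_dx = 10 + cfg.claims_repeat_model.sample(rng)
            n_rx = 5 + cfg.dmt_rx_model.sample(rng)
            n_dem = int(rng.poisson(0.5))
        elif tier == "demyelinating_only":
            n_dx = 0
            n_rx = int(rng.integers(1, 11))
            n_dem = 1 + int(rng.poisson(2))
        else:  # low_count
            n_dx = int(rng.integers(1, 11))
            n_rx = int(rng.integers(1, 11))
            n_dem = 0
        follow = max(4 * 365, 3 * (n_dx + n_dem) + 30)
        days = _distinct_days(rng, anchor + 1, anchor + follow, n_dx + n_dem - 1)
        first_concept = "ms" if n_dx else "demyelinating_disease"
        b.ev(anchor, first_concept)
        remaining_dx = n_dx - 1 if n_dx else 0
        for i, d in enumerate(days):
            b.ev(d, "ms" if i < remaining_dx else "demyelinating_disease")
        dmt = _DMT_CONCEPTS[int(rng.integers(len(_DMT_CONCEPTS)))]
        for _ in range(n_rx):
            b.add_rx(_uniform_day(rng, anchor, anchor + 3 * 365), dmt)
    else:
        bin_key = _choice(rng, cfg.emr_ms_code_count_weights)
        if bin_key == "1":
            n_dx = 1
        elif bin_key == "2":
            n_dx = 2
        else:
            n_dx = 3 + int(rng.poisson(cfg.emr_extra_ms_codes_mean))
        b.ev(anchor, "ms")
        follow = max(4 * 365, 3 * n_dx + 30)
        for d in _distinct_days(rng, anchor + 1, anchor + follow, n_dx - 1):
            b.ev(d, "ms")
        if rng.random() < cfg.dmt_capture_prob:
            dmt = _DMT_CONCEPTS[int(rng.integers(len(_DMT_CONCEPTS)))]
            for _ in range(1 + int(rng.poisson(2))):
                b.add_rx(_uniform_day(rng, anchor, anchor + 3 * 365), dmt)


def _scenario(rng: np.random.Generator, fracs: dict[str, float]) -> str:
    u = rng.random()
    acc = 0.0
    for key in sorted(fracs):
        acc += fracs[key]
        if u < acc:
            return key
    return "none"


def _inject_confounder(
    b: _PatientBuilder,
    rng: np.random.Generator,
    scenario: str,
    true_ms: bool,
    start: int,
    anchor: int,
) -> None:
    if scenario == "none":
        return
    if not true_ms:
        # a single spurious (rule-out) MS code accompanies the confounder
        b.ev(anchor, "ms")
    if scenario == "als":
        b.ev(_uniform_day(rng, start, anchor), "als")
    elif scenario in ("stroke", "tia"):
        d = max(anchor + int(rng.integers(-730, 731)), start)
        b.ev(d, scenario)
    elif scenario == "alternate":
        b.ev(_uniform_day(rng, start, anchor), "alternate_diagnosis")


def generate_population(
    config: GeneratorConfig, dialect: Dialect
) -> tuple[Bundle, list[GroundTruth]]:
    """Generate one population; deterministic given (config, dialect)."""
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    n = config.n_patients
    n_ms = int(round(n * config.ms_fraction))
    pool_k = config.controls_per_case_pool
    n_pool = min(n - n_ms, n_ms * pool_k)
    n_bg = n - n_ms - n_pool

    width = max(6, len(str(n)))
    perm = master.permutation(n)
    ids = [f"P{perm[i]:0{width}d}" for i in range(n)]
    ms_ids = ids[:n_ms]
    pool_ids = ids[n_ms : n_ms + n_pool]
    bg_ids = ids[n_ms + n_pool :]

    ms_sexes = _quota_vector(master, n_ms, config.female_fraction_ms, "F", "M")
    bg_sexes = _quota_vector(master, n_bg, config.female_fraction_nonms, "F", "M")

    records: dict[str, PatientRecord] = {}
    truths: list[GroundTruth] = []

    case_demo: list[tuple[str, int, int]] = []  # (sex, geography, birth, anchor)

    def _demographics(rng):
        band = _choice(rng, config.age_band_weights)
        lo, hi = config.age_band_ranges[band]
        age = int(rng.integers(lo, hi + 1))
        anchor = _entry_day(rng, config.entry_year_weights)
        birth = anchor - age * DAYS_PER_YEAR - int(rng.integers(0, DAYS_PER_YEAR))
        geo = f"G{int(rng.integers(config.n_geography_units)):03d}"
        return anchor, birth, geo

    for i, pid in enumerate(ms_ids):
        rng = _patient_rng(config.seed, pid)
        anchor, birth, geo = _demographics(rng)
        sex = str(ms_sexes[i])
        b = _PatientBuilder(pid, sex, birth, geo, dialect)
        start = max(anchor - _pre_entry_days(rng, config.pre_entry_years_weights), birth)
        b.enroll(start, anchor + _uniform_day(rng, 0, 5 * 365))
        _place_ms_coding(b, rng, config, anchor, dialect)
        _place_common_events(b, rng, config, True, start, anchor, dialect)
        scenario = _scenario(rng, config.exclusion_scenario_fracs)
        _inject_confounder(b, rng, scenario, True, start, anchor)
        records[pid] = b.build()
        case_demo.append((sex, geo, birth, anchor))
        truths.append(
            GroundTruth(
                patient_id=pid,
                true_ms=True,
                true_onset_day=anchor - int(rng.integers(30, 1096)),
                injected_confounder=scenario,
                anchor_day=anchor,
            )
        )

    for j, pid in enumerate(pool_ids):
        case_idx = j // pool_k if pool_k else 0
        sex, geo, birth, anchor = case_demo[case_idx]
        rng = _patient_rng(config.seed, pid)
        b = _PatientBuilder(pid, sex, birth, geo, dialect)
        start = max(anchor - _pre_entry_days(rng, config.pre_entry_years_weights), birth)
        b.enroll(start, anchor + _uniform_day(rng, 0, 5 * 365))
        _place_common_events(b, rng, config, False, start, anchor, dialect)
        scenario = _scenario(rng, config.exclusion_scenario_fracs)
        _inject_confounder(b, rng, scenario, False, start, anchor)
        records[pid] = b.build()
        truths.append(
            GroundTruth(
                patient_id=pid,
                true_ms=False,
                injected_confounder=scenario,
                anchor_day=anchor,
            )
        )

    for j, pid in enumerate(bg_ids):
        rng = _patient_rng(config.seed, pid)
        anchor, birth, geo = _demographics(rng)
        sex = str(bg_sexes[j])
        b = _PatientBuilder(pid, sex, birth, geo, dialect)
        start = max(anchor - _pre_entry_days(rng, config.pre_entry_years_weights), birth)
        b.enroll(start, anchor + _uniform_day(rng, 0, 5 * 365))
        _place_common_events(b, rng, config, False, start, anchor, dialect)
        scenario = _scenario(rng, config.exclusion_scenario_fracs)
        _inject_confounder(b, rng, scenario, False, start, anchor)
        records[pid] = b.build()
        truths.append(
            GroundTruth(
                patient_id=pid,
                true_ms=False,
                injected_confounder=scenario,
                anchor_day=anchor,
            )
        )

    ordered = dict(sorted(records.items()))
    truths.sort(key=lambda t: t.patient_id)
    return Bundle(ordered, dialect), truths


def write_ground_truth(truths: list[GroundTruth], path) -> None:
    import pandas as pd

    rows = [
        {
            "patient_id": t.patient_id,
            "true_ms": t.true_ms,
            "true_onset_date": format_day(t.true_onset_day) if t.true_onset_day else "",
            "injected_confounder": t.injected_confounder,
            "anchor_date": format_day(t.anchor_day),
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged default configurations
# ---------------------------------------------------------------------------


def default_configs(n_patients: int = 50_000, seed: int = 0) -> dict[str, GeneratorConfig]:
    """Two packaged configurations, one per dialect.

    Parameters are transcribed from the MS and matched non-MS columns of a
    published two-country MS cohort description (a US military claims
    population and a UK primary-care EMR population); sizes are scaled to
    ``n_patients``.  Weight vectors are normalized from the printed
    percentages.
    """
    S = Strat
    dod = GeneratorConfig(
        n_patients=n_patients,
        ms_fraction=0.02,
        female_fraction_ms=0.714,
        female_fraction_nonms=0.714,
        age_band_weights=_norm({"<40": 0.454, "40-59": 0.426, "60+": 0.120}),
        age_band_ranges={"<40": (7, 39), "40-59": (40, 59), "60+": (60, 85)},
        entry_year_weights=_norm(
            {"2004-2005": 0.203, "2006-2010": 0.415, "2011-2017": 0.382}
        ),
        n_geography_units=30,
        pre_entry_years_weights=_norm(
            {"1-2": 0.282, "3-5": 0.296, "6-9": 0.263, "10+": 0.153}
        ),
        dod_tier_mix=_norm(
            {"probable": 0.825, "demyelinating_only": 0.004, "low_count": 0.171}
        ),
        claims_repeat_model=NegBinModel(mean=35.0, dispersion=1.6),
        dmt_rx_model=NegBinModel(mean=25.0, dispersion=1.6),
        dmt_capture_prob=1.0,
        symptomatic_treatment_prob=S(ms=0.25, nonms=0.04),
        symptom_prevalences={
            "optic_neuritis": S(ms=0.101, nonms=0.001),
            "nerve_disorder": S(ms=0.099, nonms=0.008),
            "paresis_weakness": S(ms=0.157, nonms=0.030),
            "vertigo": S(ms=0.004, nonms=0.001),
            "spasticity_ataxia": S(ms=0.226, nonms=0.087),
            "neuritis_neuralgia": S(ms=0.255, nonms=0.102),
            "neuropathy": S(ms=0.105, nonms=0.021),
            "speech_disorder": S(ms=0.029, nonms=0.007),
            "skin_sensation_disturbance": S(ms=0.466, nonms=0.094),
            "dizziness": S(ms=0.256, nonms=0.108),
            "malaise_fatigue": S(ms=0.306, nonms=0.197),
            "vision_symptoms": S(ms=0.201, nonms=0.041),
            "bladder_symptoms": S(ms=0.214, nonms=0.156),
            "bowel_dysfunction": S(ms=0.070, nonms=0.049),
            "generalized_pain": S(ms=0.061, nonms=0.035),
            "itch": S(ms=0.049, nonms=0.041),
        },
        treated_pair_prevalences={
            "depression": S(ms=0.216, nonms=0.155),
            "hypertension": S(ms=0.195, nonms=0.181),
            "diabetes": S(ms=0.042, nonms=0.045),
        },
        comorbidity_prevalences={
            "epilepsy": S(ms=0.008, nonms=0.004),
            "asthma_copd": S(ms=0.052, nonms=0.045),
            "autoimmune_disorder": S(ms=0.003, nonms=0.002),
            "liver_disease": S(ms=0.006, nonms=0.008),
            "dyslipidemia": S(ms=0.116, nonms=0.116),
            "fracture": S(ms=0.043, nonms=0.035),
            "osteoporosis": S(ms=0.007, nonms=0.007),
        },
        cancer_prevalence=S(ms=0.034, nonms=0.035),
        infection_prevalences={
            "urinary_infection": S(ms=0.101, nonms=0.070),
            "skin_infection": S(ms=0.050, nonms=0.036),
            "respiratory_infection": S(ms=0.238, nonms=0.205),
            "pneumonia_influenza": S(ms=0.021, nonms=0.019),
            "eye_ear_infection": S(ms=0.067, nonms=0.053),
            "viral_infection": S(ms=0.082, nonms=0.062),
            "fungal_infection": S(ms=0.069, nonms=0.054),
            "meningitis": S(ms=0.0, nonms=0.0001),
        },
        hospitalized_infection_prevalence=S(ms=0.020, nonms=0.012),
        suicidal_prevalence=S(ms=0.013, nonms=0.009),
        medication_use_probs={
            "spasticity_agent": S(ms=0.162, nonms=0.056),
            "anticonvulsant": S(ms=0.211, nonms=0.067),
            "steroid": S(ms=0.255, nonms=0.128),
            "opioid": S(ms=0.384, nonms=0.268),
            "nsaid": S(ms=0.455, nonms=0.332),
            "antidepressant": S(ms=0.284, nonms=0.167),
            "antihypertensive": S(ms=0.240, nonms=0.191),
            "statin": S(ms=0.140, nonms=0.121),
            "antibiotic": S(ms=0.466, nonms=0.351),
            "oral_hypoglycemic": S(ms=0.044, nonms=0.045),
        },
        medication_mean_extra_rx={
            "spasticity_agent": 0.5,
            "anticonvulsant": 1.5,
            "steroid": 0.5,
            "opioid": 1.5,
            "nsaid": 1.5,
            "antidepressant": 3.5,
            "antihypertensive": 3.5,
            "statin": 3.0,
            "antibiotic": 1.5,
            "oral_hypoglycemic": 3.5,
        },
        smoking_weights={
            "ms": _norm({"current": 0.256, "never": 0.185, "unknown": 0.559}),
            "nonms": _norm({"current": 0.148, "never": 0.199, "unknown": 0.653}),
        },
        bmi_weights={
            "ms": _norm({"<18.5": 0.006, "18.5-25": 0.099, "25-30": 0.109,
                         "30+": 0.209, "unknown": 0.577}),
            "nonms": _norm({"<18.5": 0.005, "18.5-25": 0.097, "25-30": 0.107,
                            "30+": 0.132, "unknown": 0.659}),
        },
        seed=seed,
    )

    cprd = GeneratorConfig(
        n_patients=n_patients,
        ms_fraction=0.02,
        female_fraction_ms=0.702,
        female_fraction_nonms=0.702,
        age_band_weights=_norm({"<40": 0.396, "40-59": 0.479, "60+": 0.125}),
        age_band_ranges={"<40": (2, 39), "40-59": (40, 59), "60+": (60, 89)},
        entry_year_weights=_norm(
            {"2001-2005": 0.347, "2006-2010": 0.352, "2011-2016": 0.301}
        ),
        n_geography_units=30,
        pre_entry_years_weights=_norm(
            {"1-2": 0.124, "3-5": 0.157, "6-9": 0.205, "10+": 0.514}
        ),
        emr_ms_code_count_weights={"1": 0.33, "2": 0.33, "3+": 0.34},
        dmt_capture_prob=0.25,
        symptomatic_treatment_prob=S(ms=0.30, nonms=0.05),
        symptom_prevalences={
            "optic_neuritis": S(ms=0.121, nonms=0.001),
            "nerve_disorder": S(ms=0.038, nonms=0.001),
            "paresis_weakness": S(ms=0.142, nonms=0.010),
            "vertigo": S(ms=0.100, nonms=0.047),
            "spasticity_ataxia": S(ms=0.091, nonms=0.020),
            "neuritis_neuralgia": S(ms=0.048, nonms=0.016),
            "neuropathy": S(ms=0.029, nonms=0.003),
            "speech_disorder": S(ms=0.015, nonms=0.003),
            "skin_sensation_disturbance": S(ms=0.398, nonms=0.052),
            "dizziness": S(ms=0.168, nonms=0.078),
            "malaise_fatigue": S(ms=0.171, nonms=0.131),
            "vision_symptoms": S(ms=0.086, nonms=0.010),
            "bladder_symptoms": S(ms=0.140, nonms=0.088),
            "bowel_dysfunction": S(ms=0.092, nonms=0.077),
            "generalized_pain": S(ms=0.156, nonms=0.111),
            "itch": S(ms=0.027, nonms=0.026),
        },
        treated_pair_prevalences={
            "depression": S(ms=0.213, nonms=0.169),
            "hypertension": S(ms=0.080, nonms=0.084),
            "diabetes": S(ms=0.016, nonms=0.017),
        },
        comorbidity_prevalences={
            "epilepsy": S(ms=0.023, nonms=0.016),
            "asthma_copd": S(ms=0.160, nonms=0.147),
            "autoimmune_disorder": S(ms=0.056, nonms=0.047),
            "liver_disease": S(ms=0.010, nonms=0.011),
            "dyslipidemia": S(ms=0.056, nonms=0.050),
            "fracture": S(ms=0.214, nonms=0.197),
            "osteoporosis": S(ms=0.010, nonms=0.009),
        },
        cancer_prevalence=S(ms=0.024, nonms=0.028),
        infection_prevalences={
            "urinary_infection": S(ms=0.045, nonms=0.029),
            "skin_infection": S(ms=0.037, nonms=0.031),
            "respiratory_infection": S(ms=0.124, nonms=0.112),
            "pneumonia_influenza": S(ms=0.010, nonms=0.008),
            "eye_ear_infection": S(ms=0.049, nonms=0.032),
            "viral_infection": S(ms=0.019, nonms=0.015),
            "fungal_infection": S(ms=0.038, nonms=0.032),
            "meningitis": S(ms=0.0003, nonms=0.0001),
        },
        hospitalized_infection_prevalence=S(ms=0.019, nonms=0.008),
        suicidal_prevalence=S(ms=0.051, nonms=0.047),
        medication_use_probs={
            "spasticity_agent": S(ms=0.109, nonms=0.033),
            "anticonvulsant": S(ms=0.112, nonms=0.023),
            "steroid": S(ms=0.107, nonms=0.035),
            "opioid": S(ms=0.242, nonms=0.132),
            "nsaid": S(ms=0.226, nonms=0.146),
            "antidepressant": S(ms=0.268, nonms=0.135),
            "antihypertensive": S(ms=0.159, nonms=0.142),
            "statin": S(ms=0.074, nonms=0.065),
            "antibiotic": S(ms=0.350, nonms=0.299),
            "oral_hypoglycemic": S(ms=0.020, nonms=0.021),
        },
        medication_mean_extra_rx={
            "spasticity_agent": 1.5,
            "anticonvulsant": 2.5,
            "steroid": 0.5,
            "opioid": 1.5,
            "nsaid": 0.5,
            "antidepressant": 4.5,
            "antihypertensive": 6.5,
            "statin": 5.5,
            "antibiotic": 0.5,
            "oral_hypoglycemic": 7.5,
        },
        smoking_weights={
            "ms": _norm({"current": 0.276, "former": 0.235, "never": 0.411,
                         "unknown": 0.078}),
            "nonms": _norm({"current": 0.224, "former": 0.204, "never": 0.472,
                            "unknown": 0.100}),
        },
        bmi_weights={
            "ms": _norm({"<18.5": 0.025, "18.5-25": 0.334, "25-30": 0.269,
                         "30+": 0.198, "unknown": 0.174}),
            "nonms": _norm({"<18.5": 0.021, "18.5-25": 0.331, "25-30": 0.267,
                            "30+": 0.210, "unknown": 0.171}),
        },
        seed=seed,
    )
    return {"dod_like": dod, "cprd_like": cprd}
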