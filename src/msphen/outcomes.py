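"""Declarative outcome ascertainment at the cohort-entry (index) date.

Every comparison-table row is an :class:`OutcomeDefinition` evaluated for
each cohort member at their index date (cases: first MS code date;
controls: the matched case's index date).  Rule kinds:

``CHRONIC``
    Chronic comorbidity: present iff recorded at least once (EMR dialect)
    or on at least five distinct dates (claims dialect) at any time prior
    to or on the index date.  The claims dialect needs repetition because
    reimbursement coding repeats rule-out diagnoses.
``SYMPTOM_ANYTIME``
    Descriptive symptom row: >=1 code at any time on/before index, both
    dialects.
``TREATED_PAIR``
    Treated depression / hypertension / type-II diabetes: >=1 diagnosis
    code and >=1 respective prescription within 90 days of each other
    (symmetric), both on/before index.
``CANCER``
    EMR: >=1 cancer or history-of-cancer code.  Claims: >=5 codes within
    183 days of each other, or >=10 codes ever, or >=1 history/secondary
    code, all on/before index.
``ACUTE_WINDOW``
    Acute infection: >=1 code in the closed year [index-365, index].
``HOSPITALIZED_INFECTION``
    Claims: an inpatient infection claim in the 1-year window.  EMR: an
    infection code with a hospitalization marker within 7 days, both in
    the window.
``MENINGITIS_DOD``
    Claims-dialect meningitis: >=2 distinct-date codes plus a supporting
    treatment or symptom code, all in the 1-year window (the supporting
    set and thresholds are parameters).
``SUICIDAL``
    >=1 suicidal-behaviour code on/before index (the overdose concept is
    active only in the EMR dialect).
``MEDICATION_USE``
    Concomitant medication: prescription count of a class in the 1-year
    window; ``present`` iff count >= 1.  Anticonvulsants are attributed to
    epilepsy treatment versus MS-symptom treatment by the presence of any
    prior epilepsy diagnosis.
``CATEGORICAL_COVARIATE``
    Smoking status and BMI band from the most recent observation on/before
    index; missing -> "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .codelist import (
    CAT_HOSP_MARKER,
    CAT_SUICIDAL,
    CAT_SYMPT_TREAT,
    CAT_SYMPTOM,
    Codelist,
)
from .records import (
    DAYS_PER_HALF_YEAR,
    DAYS_PER_WEEK,
    DAYS_PER_YEAR,
    Bundle,
    ConfigError,
    DataError,
    Dialect,
    DialectError,
    PatientRecord,
)
from .matching import MatchedSet

__all__ = [
    "OutcomeKind",
    "OutcomeDefinition",
    "OutcomeResult",
    "chronic_present",
    "anytime_present",
    "treated_pair_present",
    "cancer_present",
    "acute_window_present",
    "hospitalized_infection_present",
    "meningitis_dod_present",
    "suicidal_present",
    "medication_use",
    "attribute_anticonvulsants",
    "categorize_covariates",
    "evaluate_outcome",
    "default_outcome_definitions",
    "ascertain_cohort",
]

DOD_CHRONIC_MIN_DATES = 5


class OutcomeKind(str, Enum):
    CHRONIC = "CHRONIC"
    SYMPTOM_ANYTIME = "SYMPTOM_ANYTIME"
    TREATED_PAIR = "TREATED_PAIR"
    CANCER = "CANCER"
    ACUTE_WINDOW = "ACUTE_WINDOW"
    HOSPITALIZED_INFECTION = "HOSPITALIZED_INFECTION"
    MENINGITIS_DOD = "MENINGITIS_DOD"
    SUICIDAL = "SUICIDAL"
    MEDICATION_USE = "MEDICATION_USE"
    CATEGORICAL_COVARIATE = "CATEGORICAL_COVARIATE"


@dataclass(frozen=True)
class OutcomeDefinition:
    name: str
    kind: OutcomeKind
    category: str = ""
    rx_category: str = ""  # TREATED_PAIR only
    window_days: int = DAYS_PER_YEAR
    params: tuple = ()

    def validate(self, codelist: Codelist) -> None:
        for cat in (self.category, self.rx_category):
            if cat and not codelist.concepts_in(cat):
                raise ConfigError(
                    f"outcome {self.name!r}: category {cat!r} not in codelist"
                )


@dataclass(frozen=True)
class OutcomeResult:
    patient_id: str
    outcome: str
    present: bool
    n_rx: int = 0
    category_value: str = ""


# ---------------------------------------------------------------------------
# rule primitives
# ---------------------------------------------------------------------------


def chronic_present(
    record: PatientRecord, codelist: Codelist, category: str, index_day: int
) -> bool:
    idx = record.index(codelist)
    days = idx.distinct_event_days(category, window=(None, index_day))
    if record.patient.dialect == Dialect.CLAIMS_DOD:
        return len(days) >= DOD_CHRONIC_MIN_DATES
    return len(days) >= 1


def anytime_present(
    record: PatientRecord, codelist: Codelist, category: str, index_day: int
) -> bool:
    idx = record.index(codelist)
    return bool(idx.event_days(category, window=(None, index_day)))


def treated_pair_present(
    record: PatientRecord,
    codelist: Codelist,
    dx_category: str,
    rx_category: str,
    index_day: int,
    proximity_days: int = 90,
) -> bool:
    idx = record.index(codelist)
    dx_days = idx.event_days(dx_category, window=(None, index_day))
    rx_days = idx.rx_days(rx_category, window=(None, index_day))
    if not dx_days or not rx_days:
        return False
    rx_sorted = sorted(rx_days)
    import bisect

    for d in dx_days:
        i = bisect.bisect_left(rx_sorted, d - proximity_days)
        if i < len(rx_sorted) and rx_sorted[i] <= d + proximity_days:
            return True
    return False


def cancer_present(
    record: PatientRecord,
    codelist: Codelist,
    index_day: int,
    cancer_category: str = "comorbidity:cancer",
    history_category: str = "comorbidity:cancer_history",
) -> bool:
    idx = record.index(codelist)
    history = idx.event_days(history_category, window=(None, index_day))
    if record.patient.dialect == Dialect.EMR_CPRD:
        return bool(history or idx.event_days(cancer_category, window=(None, index_day)))
    if history:
        return True
    days = idx.distinct_event_days(cancer_category, window=(None, index_day))
    if len(days) >= 10:
        return True
    # >=5 codes within a 183-day span: slide over sorted distinct dates
    for i in range(len(days) - 4):
        if days[i + 4] - days[i] <= DAYS_PER_HALF_YEAR:
            return True
    return False


def acute_window_present(
    record: PatientRecord,
    codelist: Codelist,
    category: str,
    index_day: int,
    window_days: int = DAYS_PER_YEAR,
) -> bool:
    idx = record.index(codelist)
    return bool(idx.event_days(category, window=(index_day - window_days, index_day)))


def hospitalized_infection_present(
    record: PatientRecord,
    codelist: Codelist,
    index_day: int,
    infection_categories: Sequence[str],
    window_days: int = DAYS_PER_YEAR,
) -> bool:
    idx = record.index(codelist)
    window = (index_day - window_days, index_day)
    if record.patient.dialect == Dialect.CLAIMS_DOD:
        return any(
            idx.event_days(cat, setting="inpatient", window=window)
            for cat in infection_categories
        )
    markers = idx.event_days(CAT_HOSP_MARKER, window=window)
    if not markers:
        return False
    for cat in infection_categories:
        for d in idx.event_days(cat, window=window):
            if any(abs(m - d) <= DAYS_PER_WEEK for m in markers):
                return True
    return False


def meningitis_dod_present(
    record: PatientRecord,
    codelist: Codelist,
    index_day: int,
    category: str = "infection:meningitis",
    min_distinct_dates: int = 2,
    support_categories: Sequence[str] = (
        CAT_SYMPTOM,
        CAT_SYMPT_TREAT,
        "medication:antibiotics",
    ),
    window_days: int = DAYS_PER_YEAR,
) -> bool:
    if record.patient.dialect != Dialect.CLAIMS_DOD:
        raise DialectError("meningitis_dod_present requires a CLAIMS_DOD record")
    idx = record.index(codelist)
    window = (index_day - window_days, index_day)
    if len(idx.distinct_event_days(category, window=window)) < min_distinct_dates:
        return False
    return any(
        idx.event_days(cat, window=window) or idx.rx_rows(cat, window)
        for cat in support_categories
    )


def suicidal_present(
    record: PatientRecord, codelist: Codelist, index_day: int
) -> bool:
    # dialect-inactive concepts (overdose outside the EMR dialect) are
    # already filtered by the record index
    return anytime_present(record, codelist, CAT_SUICIDAL, index_day)


def medication_use(
    record: PatientRecord,
    codelist: Codelist,
    med_category: str,
    index_day: int,
    window_days: int = DAYS_PER_YEAR,
) -> tuple[bool, int]:
    idx = record.index(codelist)
    n = idx.rx_count(med_category, (index_day - window_days, index_day))
    return n >= 1, n


def attribute_anticonvulsants(
    record: PatientRecord,
    codelist: Codelist,
    index_day: int,
    med_category: str = "medication:anticonvulsants",
    epilepsy_category: str = "comorbidity:epilepsy",
    window_days: int = DAYS_PER_YEAR,
) -> str:
    """Attribute anticonvulsant use to epilepsy versus MS-symptom treatment.

    Returns ``"none"`` without anticonvulsant use in the 1-year window;
    otherwise ``"epilepsy_treatment"`` when any epilepsy diagnosis exists
    on/before the index date, else ``"ms_symptom_treatment"``.
    """
    used, _ = medication_use(record, codelist, med_category, index_day, window_days)
    if not used:
        return "none"
    if anytime_present(record, codelist, epilepsy_category, index_day):
        return "epilepsy_treatment"
    return "ms_symptom_treatment"


SMOKING_VALUES = ("current", "former", "never", "unknown")
BMI_BANDS = ("<18.5", "18.5-25", "25-30", "30+", "unknown")


def categorize_covariates(
    record: PatientRecord, index_day: int
) -> dict[str, str]:
    """Smoking status and BMI band from the most recent observation on/before index."""
    smoking = "unknown"
    bmi_band = "unknown"
    best_smoke = best_bmi = None
    for obs in record.covariates:
        if obs.day > index_day:
            continue
        if obs.kind == "smoking":
            if best_smoke is None or obs.day >= best_smoke:
                best_smoke, smoking = obs.day, str(obs.value)
        elif obs.kind == "bmi":
            if best_bmi is None or obs.day >= best_bmi:
                value = float(obs.value)
                if value <= 0:
                    raise DataError(
                        f"patient {record.patient_id}: non-positive BMI {value}"
                    )
                best_bmi = obs.day
                if value < 18.5:
                    bmi_band = "<18.5"
                elif value < 25:
                    bmi_band = "18.5-25"
                elif value < 30:
                    bmi_band = "25-30"
                else:
                    bmi_band = "30+"
    if smoking not in SMOKING_VALUES:
        smoking = "unknown"
    return {"smoking": smoking, "bmi_band": bmi_band}


# ---------------------------------------------------------------------------
# dispatch and cohort-level evaluation
# ---------------------------------------------------------------------------

_INFECTION_SITES = (
    "infection:urinary",
    "infection:skin",
    "infection:respiratory",
    "infection:pneumonia_influenza",
    "infection:eye_ear",
    "infection:viral",
    "infection:fungal",
    "infection:meningitis",
)


def evaluate_outcome(
    definition: OutcomeDefinition,
    record: PatientRecord,
    codelist: Codelist,
    index_day: int,
) -> OutcomeResult:
    pid = record.patient_id
    kind = definition.kind
    if kind == OutcomeKind.CHRONIC:
        present = chronic_present(record, codelist, definition.category, index_day)
    elif kind == OutcomeKind.SYMPTOM_ANYTIME:
        present = anytime_present(record, codelist, definition.category, index_day)
    elif kind == OutcomeKind.TREATED_PAIR:
        present = treated_pair_present(
            record, codelist, definition.category, definition.rx_category, index_day
        )
    elif kind == OutcomeKind.CANCER:
        present = cancer_present(record, codelist, index_day)
    elif kind == OutcomeKind.ACUTE_WINDOW:
        present = acute_window_present(
            record, codelist, definition.category, index_day, definition.window_days
        )
    elif kind == OutcomeKind.HOSPITALIZED_INFECTION:
        present = hospitalized_infection_present(
            record, codelist, index_day, _INFECTION_SITES, definition.window_days
        )
    elif kind == OutcomeKind.MENINGITIS_DOD:
        if record.patient.dialect == Dialect.CLAIMS_DOD:
            present = meningitis_dod_present(record, codelist, index_day)
        else:
            present = acute_window_present(
                record, codelist, definition.category, index_day, definition.window_days
            )
    elif kind == OutcomeKind.SUICIDAL:
        present = suicidal_present(record, codelist, index_day)
    elif kind == OutcomeKind.MEDICATION_USE:
        if definition.params and definition.params[0] in (
            "no_epilepsy",
            "with_epilepsy",
        ):
            attribution = attribute_anticonvulsants(record, codelist, index_day)
            wanted = (
                "ms_symptom_treatment"
                if definition.params[0] == "no_epilepsy"
                else "epilepsy_treatment"
            )
            if attribution == wanted:
                _, n = medication_use(record, codelist, definition.category, index_day)
            else:
                n = 0
            return OutcomeResult(pid, definition.name, n >= 1, n)
        present, n = medication_use(record, codelist, definition.category, index_day)
        return OutcomeResult(pid, definition.name, present, n)
    elif kind == OutcomeKind.CATEGORICAL_COVARIATE:
        value = categorize_covariates(record, index_day)[definition.category]
        return OutcomeResult(pid, definition.name, value != "unknown", 0, value)
    else:  # pragma: no cover
        raise ConfigError(f"unknown outcome kind {kind}")
    return OutcomeResult(pid, definition.name, present)


def default_outcome_definitions(codelist: Codelist) -> list[OutcomeDefinition]:
    """The packaged outcome set mirroring the comparison-table rows."""
    K = OutcomeKind
    defs: list[OutcomeDefinition] = []
    for concept in sorted(codelist.concepts_in(CAT_SYMPTOM)):
        # one row per symptom concept; category queries on a single-concept
        # category are expressed by a dedicated per-concept definition
        defs.append(
            OutcomeDefinition(f"symptom:{concept}", K.SYMPTOM_ANYTIME, CAT_SYMPTOM,
                              params=(concept,))
        )
    defs += [
        OutcomeDefinition("treated_depression", K.TREATED_PAIR,
                          "comorbidity:depression", "medication:antidepressants"),
        OutcomeDefinition("treated_hypertension", K.TREATED_PAIR,
                          "comorbidity:hypertension", "medication:antihypertensives"),
        OutcomeDefinition("treated_diabetes", K.TREATED_PAIR,
                          "comorbidity:diabetes", "medication:oral_hypoglycemics"),
        OutcomeDefinition("epilepsy", K.CHRONIC, "comorbidity:epilepsy"),
        OutcomeDefinition("asthma_copd", K.CHRONIC, "comorbidity:asthma_copd"),
        OutcomeDefinition("autoimmune_disorders", K.CHRONIC, "comorbidity:autoimmune"),
        OutcomeDefinition("liver_disease", K.CHRONIC, "comorbidity:liver_disease"),
        OutcomeDefinition("dyslipidemia", K.CHRONIC, "comorbidity:dyslipidemia"),
        OutcomeDefinition("fracture", K.CHRONIC, "comorbidity:fracture"),
        OutcomeDefinition("osteoporosis", K.CHRONIC, "comorbidity:osteoporosis"),
        OutcomeDefinition("cancer", K.CANCER, "comorbidity:cancer"),
        OutcomeDefinition("suicidal_behaviors", K.SUICIDAL, CAT_SUICIDAL),
        OutcomeDefinition("hospitalized_infections", K.HOSPITALIZED_INFECTION),
    ]
    for site in _INFECTION_SITES:
        name = f"infection:{site.split(':', 1)[1]}"
        if site == "infection:meningitis":
            defs.append(OutcomeDefinition(name, K.MENINGITIS_DOD, site))
        else:
            defs.append(OutcomeDefinition(name, K.ACUTE_WINDOW, site))
    med_classes = sorted(
        c for c in codelist.categories if c.startswith("medication:")
    )
    for cat in med_classes:
        name = f"medication:{cat.split(':', 1)[1]}"
        if cat == "medication:anticonvulsants":
            defs.append(
                OutcomeDefinition(
                    "medication:anticonvulsants_no_epilepsy", K.MEDICATION_USE,
                    cat, params=("no_epilepsy",)
                )
            )
            defs.append(
                OutcomeDefinition(
                    "medication:anticonvulsants_with_epilepsy", K.MEDICATION_USE,
                    cat, params=("with_epilepsy",)
                )
            )
        else:
            defs.append(OutcomeDefinition(name, K.MEDICATION_USE, cat))
    defs += [
        OutcomeDefinition("smoking", K.CATEGORICAL_COVARIATE, "smoking"),
        OutcomeDefinition("bmi_band", K.CATEGORICAL_COVARIATE, "bmi_band"),
    ]
    for d in defs:
        if d.kind not in (K.CATEGORICAL_COVARIATE, K.HOSPITALIZED_INFECTION):
            d.validate(codelist)
    return defs


def ascertain_cohort(
    bundle: Bundle,
    cohort_members: Sequence,
    matched_sets: Sequence[MatchedSet],
    codelist: Codelist,
    definitions: Optional[Sequence[OutcomeDefinition]] = None,
) -> pd.DataFrame:
    """Evaluate every outcome for every case and matched control.

    Returns a tidy frame with columns ``patient_id, arm, outcome, present,
    n_rx, category_value``; controls anchor on their case's index date.
    Events strictly after a patient's index date never influence a result.
    """
    if definitions is None:
        definitions = default_outcome_definitions(codelist)
    index_of: dict[str, int] = {}
    arm_of: dict[str, str] = {}
    for m in cohort_members:
        index_of[m.patient_id] = m.first_ms_date
        arm_of[m.patient_id] = "ms"
    for s in matched_sets:
        for cid in s.control_ids:
            index_of[cid] = s.index_date
            arm_of[cid] = "nonms"

    rows = []
    for pid, index_day in index_of.items():
        record = bundle[pid]
        arm = arm_of[pid]
        idx = record.index(codelist)
        for d in definitions:
            if d.kind == OutcomeKind.SYMPTOM_ANYTIME and d.params:
                concept = d.params[0]
                present = any(
                    e.concept == concept and e.day <= index_day
                    for e in record.events
                )
                res = OutcomeResult(pid, d.name, present)
            else:
                res = evaluate_outcome(d, record, codelist, index_day)
            rows.append(
                (pid, arm, res.outcome, res.present, res.n_rx, res.category_value)
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "arm", "outcome", "present", "n_rx", "category_value"],
    )
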