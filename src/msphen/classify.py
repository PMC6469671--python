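"""Database-specific MS case algorithms, exclusions and the incident filter.

Two tiered rule sets are implemented, one per dialect.

Claims dialect (``CLAIMS_DOD``).  A gate first requires at least one MS or
demyelinating-disease diagnosis AND at least one prescription for an MS
disease-modifying treatment (DMT) or dalfampridine.  Then:

* ``PROBABLE`` — >=10 distinct dates with MS-or-demyelinating diagnoses and
  >=5 DMT prescriptions, or >=5 distinct MS diagnosis dates and >=10 DMT
  prescriptions;
* ``POSSIBLE_DEMYELINATING_ONLY`` — demyelinating codes without any MS code,
  plus >=1 DMT prescription;
* ``POSSIBLE_LOW_COUNT`` — one to ten distinct MS diagnosis dates and one to
  ten DMT prescriptions.

EMR dialect (``EMR_CPRD``).  Chronic diagnoses appear rarely and DMTs are
mostly uncaptured, so supporting symptom / symptomatic-treatment codes stand
in for repetition:

* ``PROBABLE`` — >=2 distinct MS diagnosis dates plus supporting treatment
  and/or symptom codes;
* ``POSSIBLE_CPRD_SUPPORTED`` — >=1 MS diagnosis plus support (but not
  probable);
* ``POSSIBLE_CPRD_UNSUPPORTED`` — >=2 distinct MS dates, no support;
* ``UNLIKELY`` — a single MS code and no support (reported, never enrolled).

All MS / demyelinating count thresholds are evaluated on *distinct dates*,
in both dialects and in the exclusion rules; DMT prescriptions are counted
as prescription rows (sum of issues).  Shared exclusions: (1) ALS coded at
any time; (2) an alternate diagnosis present with few MS codes (exactly one
in the EMR dialect, fewer than five in the claims dialect); (3) stroke or
TIA coded at any time prior to, or up to 6 months (183 days) after, the
first MS code, again with few MS codes.  Incident cases additionally need
one full year of enrollment immediately before the first MS code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional

from .codelist import (
    CAT_DEMYELINATING,
    CAT_DMT,
    CAT_MS,
    CAT_SYMPT_TREAT,
    CAT_SYMPTOM,
    EXCL_ALS,
    EXCL_ALTERNATE,
    EXCL_STROKE,
    EXCL_TIA,
    Codelist,
)
from .records import (
    DAYS_PER_HALF_YEAR,
    DAYS_PER_YEAR,
    Bundle,
    Dialect,
    DialectError,
    PatientRecord,
    periods_cover,
)

__all__ = [
    "Tier",
    "ExclusionReason",
    "CaseClassification",
    "classify_dod",
    "classify_cprd",
    "classify_record",
    "apply_exclusions",
    "incident_filter",
    "build_ms_cohort",
    "CohortResult",
    "COHORT_TIERS",
]


class Tier(str, Enum):
    PROBABLE = "PROBABLE"
    POSSIBLE_DEMYELINATING_ONLY = "POSSIBLE_DEMYELINATING_ONLY"
    POSSIBLE_LOW_COUNT = "POSSIBLE_LOW_COUNT"
    POSSIBLE_CPRD_SUPPORTED = "POSSIBLE_CPRD_SUPPORTED"
    POSSIBLE_CPRD_UNSUPPORTED = "POSSIBLE_CPRD_UNSUPPORTED"
    UNLIKELY = "UNLIKELY"
    NON_CASE = "NON_CASE"


#: tiers whose members enter the MS cohort (UNLIKELY never does)
COHORT_TIERS = frozenset(
    {
        Tier.PROBABLE,
        Tier.POSSIBLE_DEMYELINATING_ONLY,
        Tier.POSSIBLE_LOW_COUNT,
        Tier.POSSIBLE_CPRD_SUPPORTED,
        Tier.POSSIBLE_CPRD_UNSUPPORTED,
    }
)

#: coarse certainty grouping used for validation reporting
TIER_GROUPS = {
    Tier.PROBABLE: "probable",
    Tier.POSSIBLE_DEMYELINATING_ONLY: "possible",
    Tier.POSSIBLE_LOW_COUNT: "possible",
    Tier.POSSIBLE_CPRD_SUPPORTED: "possible",
    Tier.POSSIBLE_CPRD_UNSUPPORTED: "possible",
    Tier.UNLIKELY: "unlikely",
}


class ExclusionReason(str, Enum):
    NONE = "none"
    ALS_ANY_TIME = "als_any_time"
    ALTERNATE_DX_FEW_MS_CODES = "alternate_dx_few_ms_codes"
    STROKE_TIA_NEAR_MS = "stroke_tia_near_ms"


@dataclass(frozen=True)
class CaseClassification:
    patient_id: str
    tier: Tier
    first_ms_date: Optional[int]
    n_ms_dx_dates: int
    n_demyelinating_dx_dates: int
    n_dmt_rx: int
    dialect: Dialect
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    incident: bool = False


def _counts(record: PatientRecord, codelist: Codelist):
    idx = record.index(codelist)
    ms_days = idx.distinct_event_days(CAT_MS)
    dem_days = idx.distinct_event_days(CAT_DEMYELINATING)
    union_days = idx.distinct_event_days(CAT_MS, CAT_DEMYELINATING)
    n_dmt = idx.rx_count(CAT_DMT)
    return ms_days, dem_days, union_days, n_dmt


def classify_dod(record: PatientRecord, codelist: Codelist) -> CaseClassification:
    """Apply the claims-dialect tiered case algorithm to one record."""
    if record.patient.dialect != Dialect.CLAIMS_DOD:
        raise DialectError(
            f"classify_dod requires CLAIMS_DOD, got {record.patient.dialect}"
        )
    ms_days, dem_days, union_days, n_dmt = _counts(record, codelist)
    n_ms, n_dem, n_union = len(ms_days), len(dem_days), len(union_days)

    tier = Tier.NON_CASE
    if n_union >= 1 and n_dmt >= 1:  # inclusion gate
        if (n_union >= 10 and n_dmt >= 5) or (n_ms >= 5 and n_dmt >= 10):
            tier = Tier.PROBABLE
        elif n_dem >= 1 and n_ms == 0:
            tier = Tier.POSSIBLE_DEMYELINATING_ONLY
        elif 1 <= n_ms <= 10 and 1 <= n_dmt <= 10:
            tier = Tier.POSSIBLE_LOW_COUNT

    first_ms: Optional[int] = ms_days[0] if ms_days else None
    if first_ms is None and tier == Tier.POSSIBLE_DEMYELINATING_ONLY:
        # no MS code exists for this tier; anchor entry on the first
        # demyelinating-disease code instead
        first_ms = dem_days[0]
    return CaseClassification(
        record.patient_id, tier, first_ms, n_ms, n_dem, n_dmt, Dialect.CLAIMS_DOD
    )


def _has_support(record: PatientRecord, codelist: Codelist) -> bool:
    idx = record.index(codelist)
    for cat in (CAT_SYMPTOM, CAT_SYMPT_TREAT):
        if idx.event_days(cat) or idx.rx_rows(cat):
            return True
    return False


def classify_cprd(record: PatientRecord, codelist: Codelist) -> CaseClassification:
    """Apply the EMR-dialect tiered case algorithm to one record."""
    if record.patient.dialect != Dialect.EMR_CPRD:
        raise DialectError(
            f"classify_cprd requires EMR_CPRD, got {record.patient.dialect}"
        )
    ms_days, dem_days, _, n_dmt = _counts(record, codelist)
    n_ms = len(ms_days)
    support = _has_support(record, codelist)

    if n_ms == 0:
        tier = Tier.NON_CASE
    elif n_ms >= 2 and support:
        tier = Tier.PROBABLE
    elif support:  # n_ms == 1
        tier = Tier.POSSIBLE_CPRD_SUPPORTED
    elif n_ms >= 2:
        tier = Tier.POSSIBLE_CPRD_UNSUPPORTED
    else:
        tier = Tier.UNLIKELY

    return CaseClassification(
        record.patient_id,
        tier,
        ms_days[0] if ms_days else None,
        n_ms,
        len(dem_days),
        n_dmt,
        Dialect.EMR_CPRD,
    )


def classify_record(record: PatientRecord, codelist: Codelist) -> CaseClassification:
    if record.patient.dialect == Dialect.CLAIMS_DOD:
        return classify_dod(record, codelist)
    return classify_cprd(record, codelist)


def apply_exclusions(
    record: PatientRecord, cls: CaseClassification, codelist: Codelist
) -> CaseClassification:
    """Flag the shared exclusion rules on a classified record.

    Checked in fixed priority order: ALS at any time, then alternate
    diagnosis with few MS codes, then stroke/TIA up to 6 months after the
    first MS code with few MS codes.
    """
    idx = record.index(codelist)
    few_ms = (
        cls.n_ms_dx_dates == 1
        if cls.dialect == Dialect.EMR_CPRD
        else cls.n_ms_dx_dates < 5
    )

    reason = ExclusionReason.NONE
    if idx.event_days(EXCL_ALS):
        reason = ExclusionReason.ALS_ANY_TIME
    elif few_ms and idx.event_days(EXCL_ALTERNATE):
        reason = ExclusionReason.ALTERNATE_DX_FEW_MS_CODES
    elif few_ms and cls.first_ms_date is not None:
        cutoff = cls.first_ms_date + DAYS_PER_HALF_YEAR
        stroke_tia = idx.event_days(EXCL_STROKE) + idx.event_days(EXCL_TIA)
        if any(d <= cutoff for d in stroke_tia):
            reason = ExclusionReason.STROKE_TIA_NEAR_MS

    return replace(
        cls, excluded=reason != ExclusionReason.NONE, exclusion_reason=reason
    )


def incident_filter(
    record: PatientRecord, cls: CaseClassification
) -> CaseClassification:
    """Require one full year of enrollment immediately before the first MS code.

    ``incident`` is true iff one merged enrollment period covers the closed
    interval [first_ms_date - 365, first_ms_date].
    """
    if cls.first_ms_date is None:
        return replace(cls, incident=False)
    ok = periods_cover(
        record.enrollment, cls.first_ms_date - DAYS_PER_YEAR, cls.first_ms_date
    )
    return replace(cls, incident=ok)


@dataclass
class CohortResult:
    """Output of :func:`build_ms_cohort`."""

    members: list[CaseClassification]
    classifications: dict[str, CaseClassification]
    tier_counts: Counter
    exclusion_counts: Counter

    @property
    def member_ids(self) -> list[str]:
        return [m.patient_id for m in self.members]


def build_ms_cohort(bundle: Bundle, codelist: Codelist) -> CohortResult:
    """Classify every record and assemble the incident MS cohort.

    Members are patients in a case tier (probable or any possible subtype;
    UNLIKELY is reported but never enrolled), not excluded, and incident.
    Cohort entry date is the classification's first MS date.
    """
    classifications: dict[str, CaseClassification] = {}
    members: list[CaseClassification] = []
    tier_counts: Counter = Counter()
    excl_counts: Counter = Counter()
    for record in bundle:
        cls = classify_record(record, codelist)
        cls = apply_exclusions(record, cls, codelist)
        cls = incident_filter(record, cls)
        classifications[cls.patient_id] = cls
        tier_counts[cls.tier] += 1
        if cls.excluded:
            excl_counts[cls.exclusion_reason] += 1
        if cls.tier in COHORT_TIERS and not cls.excluded and cls.incident:
            members.append(cls)
    members.sort(key=lambda c: (c.first_ms_date, c.patient_id))
    return CohortResult(members, classifications, tier_counts, excl_counts)
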