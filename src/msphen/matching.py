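"""Exact 1:k matching of MS-free controls to incident MS cases.

Each incident case is matched to up to ten controls sharing the exact
:class:`MatchKey`: completed age in years at the case's cohort-entry
(index) date, sex, calendar month and year of cohort entry, and geographic
unit (practice in the EMR dialect, region in the claims dialect).

Controls must be MS-free at any time in the record (no MS *or*
demyelinating-disease code ever), must satisfy the same one-year
prior-enrollment requirement as cases, and adopt the case's index date for
all later look-back ascertainment.  Controls are sampled uniformly without
replacement, and a control serves at most one case across the whole run;
cases are processed in ascending index-date then patient-id order, so a
run is deterministic given its seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .codelist import CAT_DEMYELINATING, CAT_MS, Codelist
from .records import (
    DAYS_PER_YEAR,
    Bundle,
    ConfigError,
    PatientRecord,
    age_years_at,
    periods_cover,
)
from .classify import CaseClassification

__all__ = ["MatchKey", "MatchedSet", "match_key", "eligible_controls", "match_cohort"]


@dataclass(frozen=True)
class MatchKey:
    age_years_at_entry: int
    sex: str
    entry_month: tuple[int, int]  # (year, month)
    geography: str


@dataclass(frozen=True)
class MatchedSet:
    case_id: str
    index_date: int
    control_ids: tuple[str, ...]
    match_key: MatchKey


def match_key(record: PatientRecord, index_day: int) -> MatchKey:
    """The exact-match key of a patient evaluated at an index date."""
    d = _dt.date.fromordinal(int(index_day))
    return MatchKey(
        age_years_at(record.patient.birth_day, index_day),
        record.patient.sex,
        (d.year, d.month),
        record.patient.geography,
    )


def _is_ms_free(record: PatientRecord, codelist: Codelist) -> bool:
    idx = record.index(codelist)
    return not idx.event_days(CAT_MS) and not idx.event_days(CAT_DEMYELINATING)


def eligible_controls(
    bundle: Bundle,
    classifications: Mapping[str, CaseClassification],
    key: MatchKey,
    index_day: int,
    codelist: Codelist,
) -> set[str]:
    """Identifiers of candidates eligible to control a case with this key.

    Candidates have no MS or demyelinating code at any time, are not
    (excluded or unlikely) MS patients, have enrollment covering the year
    up to the index date, and match the key exactly.
    """
    out: set[str] = set()
    for record in bundle:
        pid = record.patient_id
        cls = classifications.get(pid)
        if cls is not None and cls.tier.value != "NON_CASE":
            continue
        if not _is_ms_free(record, codelist):
            continue
        if not periods_cover(record.enrollment, index_day - DAYS_PER_YEAR, index_day):
            continue
        if match_key(record, index_day) == key:
            out.add(pid)
    return out


class _CandidatePool:
    """Candidates bucketed by (sex, geography) with vectorized age filtering."""

    def __init__(self, bundle: Bundle, classifications, codelist: Codelist) -> None:
        buckets: dict[tuple[str, str], list[tuple[str, int, tuple]]] = {}
        for record in bundle:
            pid = record.patient_id
            cls = classifications.get(pid)
            if cls is not None and cls.tier.value != "NON_CASE":
                continue
            if not _is_ms_free(record, codelist):
                continue
            buckets.setdefault((record.patient.sex, record.patient.geography), []).append(
                (pid, record.patient.birth_day, tuple(record.enrollment))
            )
        self._buckets = {}
        for k, rows in buckets.items():
            rows.sort()  # deterministic candidate order by patient id
            ids = [r[0] for r in rows]
            births = np.array([r[1] for r in rows], dtype=np.int64)
            periods = [r[2] for r in rows]
            self._buckets[k] = (ids, births, periods)

    def candidates(self, key: MatchKey, index_day: int, used: set[str]) -> list[str]:
        bucket = self._buckets.get((key.sex, key.geography))
        if bucket is None:
            return []
        ids, births, periods = bucket
        # completed age a at index  <=>  birth in the a-th 365-day band
        lo = index_day - DAYS_PER_YEAR * (key.age_years_at_entry + 1) + 1
        hi = index_day - DAYS_PER_YEAR * key.age_years_at_entry
        sel = np.nonzero((births >= lo) & (births <= hi))[0]
        out = []
        start = index_day - DAYS_PER_YEAR
        for i in sel:
            pid = ids[i]
            if pid in used:
                continue
            if periods_cover(periods[i], start, index_day):
                out.append(pid)
        return out


def match_cohort(
    cases: Sequence[CaseClassification],
    bundle: Bundle,
    classifications: Mapping[str, CaseClassification],
    codelist: Codelist,
    ratio: int = 10,
    seed: int = 0,
) -> list[MatchedSet]:
    """Match up to *ratio* controls to every incident case.

    Cases with no eligible control are retained with an empty control list
    (the MS cohort size is fixed before matching).
    """
    if ratio < 1:
        raise ConfigError(f"matching ratio must be >= 1, got {ratio}")
    rng = np.random.default_rng(seed)
    pool = _CandidatePool(bundle, classifications, codelist)
    used: set[str] = set()
    out: list[MatchedSet] = []
    ordered = sorted(cases, key=lambda c: (c.first_ms_date, c.patient_id))
    for case in ordered:
        record = bundle[case.patient_id]
        index_day = case.first_ms_date
        key = match_key(record, index_day)
        candidates = pool.candidates(key, index_day, used)
        k = min(ratio, len(candidates))
        if k:
            picked = rng.choice(len(candidates), size=k, replace=False)
            chosen = tuple(sorted(candidates[i] for i in picked))
        else:
            chosen = ()
        used.update(chosen)
        out.append(MatchedSet(case.patient_id, index_day, chosen, key))
    return out
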