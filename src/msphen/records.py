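"""Dialect-tagged longitudinal coded health records.

The unit of analysis everywhere in this package is a :class:`PatientRecord`:
one person's demographics, database enrollment periods, coded clinical events
and prescriptions, tagged with the *dialect* of the source system.  Two
dialects are modelled:

``CLAIMS_DOD``
    A reimbursement-driven claims system in which a diagnosis code is entered
    at every billable encounter, including screening and rule-out visits, so
    chronic diagnoses repeat many times, and drug capture is complete.
``EMR_CPRD``
    A clinician-maintained primary-care record in which a confirmed chronic
    diagnosis may be coded only once or twice and specialty-administered
    drugs (e.g. MS disease-modifying infusions) are mostly absent.

Dates are ISO-8601 strings in files and integer day numbers (proleptic
Gregorian ordinals, :meth:`datetime.date.toordinal`) in memory.  All
intervals are closed unless an operation states otherwise, and fixed
interval lengths are used throughout: 1 year = 365 days, 6 months = 183
days, 1 week = 7 days.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .codelist import Codelist

__all__ = [
    "DAYS_PER_YEAR",
    "DAYS_PER_HALF_YEAR",
    "DAYS_PER_WEEK",
    "Dialect",
    "SchemaError",
    "DataError",
    "DialectError",
    "ConfigError",
    "Patient",
    "EnrollmentPeriod",
    "CodedEvent",
    "Prescription",
    "CovariateObs",
    "PatientRecord",
    "Bundle",
    "parse_day",
    "format_day",
    "merge_periods",
    "periods_cover",
    "age_years_at",
    "count_distinct_dates",
    "first_date_of",
    "count_rx",
    "read_bundle",
    "write_bundle",
]

DAYS_PER_YEAR = 365
DAYS_PER_HALF_YEAR = 183
DAYS_PER_WEEK = 7


class Dialect(str, Enum):
    """Coding dialect of a record bundle; rules dispatch on it."""

    CLAIMS_DOD = "CLAIMS_DOD"
    EMR_CPRD = "EMR_CPRD"


class SchemaError(ValueError):
    """A bundle file does not conform to the expected delimited schema."""


class DataError(ValueError):
    """A row-level data problem (unparseable date, impossible value)."""


class DialectError(TypeError):
    """An operation was dispatched on a record of the wrong dialect."""


class ConfigError(ValueError):
    """A configuration problem (unknown category, bad parameter)."""


def parse_day(text: str, *, context: str = "") -> int:
    """Parse an ISO-8601 date string to an integer day number."""
    try:
        return _dt.date.fromisoformat(str(text).strip()).toordinal()
    except ValueError as exc:
        raise DataError(f"unparseable date {text!r}{context}") from exc


def format_day(day: int) -> str:
    return _dt.date.fromordinal(int(day)).isoformat()


def age_years_at(birth_day: int, day: int) -> int:
    """Completed years of age, using fixed 365-day years."""
    return (int(day) - int(birth_day)) // DAYS_PER_YEAR


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str  # "F" | "M"
    birth_day: int
    geography: str
    dialect: Dialect


@dataclass(frozen=True)
class EnrollmentPeriod:
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise DataError(
                f"enrollment period start {format_day(self.start_day)} after "
                f"end {format_day(self.end_day)}"
            )


@dataclass(frozen=True)
class CodedEvent:
    day: int
    concept: str
    setting: str = "outpatient"  # "outpatient" | "inpatient"


@dataclass(frozen=True)
class Prescription:
    day: int
    drug_concept: str
    n_issues: int = 1

    def __post_init__(self) -> None:
        if self.n_issues < 1:
            raise DataError(f"n_issues must be positive, got {self.n_issues}")


@dataclass(frozen=True)
class CovariateObs:
    """A dated lifestyle observation (smoking status or a BMI value)."""

    day: int
    kind: str  # "smoking" | "bmi"
    value: str | float


def merge_periods(periods: Iterable[EnrollmentPeriod]) -> list[EnrollmentPeriod]:
    """Sort and merge overlapping or contiguous enrollment periods."""
    ordered = sorted(periods, key=lambda p: (p.start_day, p.end_day))
    merged: list[EnrollmentPeriod] = []
    for p in ordered:
        if merged and p.start_day <= merged[-1].end_day + 1:
            if p.end_day > merged[-1].end_day:
                merged[-1] = EnrollmentPeriod(merged[-1].start_day, p.end_day)
        else:
            merged.append(EnrollmentPeriod(p.start_day, p.end_day))
    return merged


def periods_cover(periods: Sequence[EnrollmentPeriod], start: int, end: int) -> bool:
    """True iff one merged period covers the whole closed interval [start, end]."""
    return any(p.start_day <= start and p.end_day >= end for p in periods)


@dataclass
class PatientRecord:
    """One person's full longitudinal record in one dialect."""

    patient: Patient
    enrollment: list[EnrollmentPeriod] = field(default_factory=list)
    events: list[CodedEvent] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)
    covariates: list[CovariateObs] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.enrollment = merge_periods(self.enrollment)
        self._index_cache: tuple[int, "_RecordIndex"] | None = None

    @property
    def patient_id(self) -> str:
        return self.patient.patient_id

    def index(self, codelist: Codelist) -> "_RecordIndex":
        cached = getattr(self, "_index_cache", None)
        if cached is not None and cached[0] == id(codelist):
            return cached[1]
        idx = _RecordIndex(self, codelist)
        self._index_cache = (id(codelist), idx)
        return idx


class _RecordIndex:
    """Per-record category -> date lookups, built once per (record, codelist)."""

    def __init__(self, record: PatientRecord, codelist: Codelist) -> None:
        self._codelist = codelist
        dialect = record.patient.dialect
        ev: dict[str, list[tuple[int, str]]] = {}
        for e in record.events:
            cat = codelist.category_of(e.concept)
            if cat is None or not codelist.active_in(e.concept, dialect):
                continue
            ev.setdefault(cat, []).append((e.day, e.setting))
        self._events = {c: sorted(v) for c, v in ev.items()}
        rx: dict[str, list[tuple[int, int]]] = {}
        for r in record.prescriptions:
            cat = codelist.category_of(r.drug_concept)
            if cat is None or not codelist.active_in(r.drug_concept, dialect):
                continue
            rx.setdefault(cat, []).append((r.day, r.n_issues))
        self._rx = {c: sorted(v) for c, v in rx.items()}

    def event_days(
        self,
        category: str,
        *,
        setting: str | None = None,
        window: tuple[Optional[int], Optional[int]] | None = None,
    ) -> list[int]:
        """All event days (with repeats) of a category, optionally filtered."""
        rows = self._events.get(category, [])
        lo, hi = window if window is not None else (None, None)
        return [
            d
            for d, s in rows
            if (setting is None or s == setting)
            and (lo is None or d >= lo)
            and (hi is None or d <= hi)
        ]

    def distinct_event_days(self, *categories: str, **kw) -> list[int]:
        days: set[int] = set()
        for cat in categories:
            days.update(self.event_days(cat, **kw))
        return sorted(days)

    def rx_rows(
        self, category: str, window: tuple[Optional[int], Optional[int]] | None = None
    ) -> list[tuple[int, int]]:
        rows = self._rx.get(category, [])
        lo, hi = window if window is not None else (None, None)
        return [
            (d, n)
            for d, n in rows
            if (lo is None or d >= lo) and (hi is None or d <= hi)
        ]

    def rx_count(
        self, category: str, window: tuple[Optional[int], Optional[int]] | None = None
    ) -> int:
        return sum(n for _, n in self.rx_rows(category, window))

    def rx_days(
        self, category: str, window: tuple[Optional[int], Optional[int]] | None = None
    ) -> list[int]:
        return [d for d, _ in self.rx_rows(category, window)]


def _check_category(codelist: Codelist, category: str) -> None:
    if not codelist.concepts_in(category):
        raise ConfigError(f"category {category!r} has no concepts in the codelist")


def count_distinct_dates(
    record: PatientRecord,
    codelist: Codelist,
    category: str,
    window: tuple[Optional[int], Optional[int]] | None = None,
) -> int:
    """Number of distinct calendar dates with >=1 event of *category*.

    Two codes of the category on one date count once; the window, when
    given, is a closed interval of day numbers (either endpoint may be
    ``None`` for unbounded).
    """
    _check_category(codelist, category)
    return len(record.index(codelist).distinct_event_days(category, window=window))


def first_date_of(
    record: PatientRecord, codelist: Codelist, category: str
) -> Optional[int]:
    """Earliest event day of *category*, or ``None`` when absent."""
    days = record.index(codelist).distinct_event_days(category)
    return days[0] if days else None


def count_rx(
    record: PatientRecord,
    codelist: Codelist,
    category: str,
    window: tuple[Optional[int], Optional[int]] | None = None,
) -> int:
    """Prescription count (sum of ``n_issues``) of a drug category."""
    _check_category(codelist, category)
    return record.index(codelist).rx_count(category, window)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_PATIENT_COLS = ["patient_id", "sex", "birth_date", "geography", "dialect"]
_ENROLL_COLS = ["patient_id", "start_date", "end_date"]
_EVENT_COLS = ["patient_id", "event_date", "concept", "setting"]
_RX_COLS = ["patient_id", "rx_date", "drug_concept", "n_issues"]
_COV_COLS = ["patient_id", "obs_date", "kind", "value"]


@dataclass
class Bundle:
    """An ordered collection of records sharing one dialect."""

    records: dict[str, PatientRecord]
    dialect: Dialect
    unknown_concepts: frozenset[str] = frozenset()

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, patient_id: str) -> PatientRecord:
        return self.records[patient_id]


def _read_csv(path: Path, required: list[str], optional: bool = False) -> pd.DataFrame:
    if not path.exists():
        if optional:
            return pd.DataFrame(columns=required)
        raise SchemaError(f"missing bundle file {path.name}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def _parse_dates(df: pd.DataFrame, col: str, fname: str) -> list[int]:
    out = []
    for i, text in enumerate(df[col]):
        # header is line 1, so data row i is file line i + 2
        out.append(parse_day(text, context=f" ({fname} line {i + 2})"))
    return out


def read_bundle(directory: str | Path, codelist: Codelist) -> Bundle:
    """Read a four-file (plus optional covariates) bundle from *directory*.

    Files: ``patients.csv``, ``enrollment.csv``, ``events.csv``,
    ``prescriptions.csv`` and optionally ``covariates.csv``; comma-separated,
    UTF-8, header row.  Unknown concepts are retained on the returned bundle
    for reporting but their events are ignored by category queries.
    """
    directory = Path(directory)
    pats = _read_csv(directory / "patients.csv", _PATIENT_COLS)
    enr = _read_csv(directory / "enrollment.csv", _ENROLL_COLS)
    evs = _read_csv(directory / "events.csv", _EVENT_COLS)
    rxs = _read_csv(directory / "prescriptions.csv", _RX_COLS)
    covs = _read_csv(directory / "covariates.csv", _COV_COLS, optional=True)

    if pats["patient_id"].duplicated().any():
        dupes = pats.loc[pats["patient_id"].duplicated(), "patient_id"].tolist()
        raise DataError(f"duplicate patient_id in patients.csv: {dupes[:5]}")

    dialects = set(pats["dialect"])
    if len(dialects) > 1:
        raise DataError(f"bundle mixes dialects: {sorted(dialects)}")
    try:
        dialect = Dialect(next(iter(dialects))) if dialects else Dialect.CLAIMS_DOD
    except ValueError as exc:
        raise DataError(f"unknown dialect {dialects}") from exc

    records: dict[str, PatientRecord] = {}
    for row, birth in zip(
        pats.itertuples(index=False), _parse_dates(pats, "birth_date", "patients.csv")
    ):
        records[row.patient_id] = PatientRecord(
            Patient(row.patient_id, row.sex, birth, row.geography, dialect)
        )

    def _target(pid: str, fname: str, line: int) -> PatientRecord:
        rec = records.get(pid)
        if rec is None:
            raise DataError(f"{fname} line {line}: unknown patient_id {pid!r}")
        return rec

    starts = _parse_dates(enr, "start_date", "enrollment.csv")
    ends = _parse_dates(enr, "end_date", "enrollment.csv")
    for i, row in enumerate(enr.itertuples(index=False)):
        _target(row.patient_id, "enrollment.csv", i + 2).enrollment.append(
            EnrollmentPeriod(starts[i], ends[i])
        )

    unknown: set[str] = set()
    days = _parse_dates(evs, "event_date", "events.csv")
    for i, row in enumerate(evs.itertuples(index=False)):
        if codelist.category_of(row.concept) is None:
            unknown.add(row.concept)
        _target(row.patient_id, "events.csv", i + 2).events.append(
            CodedEvent(days[i], row.concept, row.setting or "outpatient")
        )

    days = _parse_dates(rxs, "rx_date", "prescriptions.csv")
    for i, row in enumerate(rxs.itertuples(index=False)):
        if codelist.category_of(row.drug_concept) is None:
            unknown.add(row.drug_concept)
        n = int(row.n_issues) if row.n_issues else 1
        _target(row.patient_id, "prescriptions.csv", i + 2).prescriptions.append(
            Prescription(days[i], row.drug_concept, n)
        )

    days = _parse_dates(covs, "obs_date", "covariates.csv") if len(covs) else []
    for i, row in enumerate(covs.itertuples(index=False)):
        value: str | float = row.value
        if row.kind == "bmi":
            value = float(row.value)
        _target(row.patient_id, "covariates.csv", i + 2).covariates.append(
            CovariateObs(days[i], row.kind, value)
        )

    for rec in records.values():
        rec.enrollment = merge_periods(rec.enrollment)
        if rec.events and min(e.day for e in rec.events) < rec.patient.birth_day:
            raise DataError(
                f"patient {rec.patient_id}: event precedes birth date"
            )

    ordered = dict(sorted(records.items()))
    return Bundle(ordered, dialect, frozenset(unknown))


def write_bundle(bundle: Bundle, directory: str | Path) -> None:
    """Write a bundle in canonical order (sorted ids, ascending dates)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pats, enr, evs, rxs, covs = [], [], [], [], []
    for pid in sorted(bundle.records):
        rec = bundle.records[pid]
        p = rec.patient
        pats.append((pid, p.sex, format_day(p.birth_day), p.geography, p.dialect.value))
        for per in merge_periods(rec.enrollment):
            enr.append((pid, format_day(per.start_day), format_day(per.end_day)))
        for e in sorted(rec.events, key=lambda e: (e.day, e.concept, e.setting)):
            evs.append((pid, format_day(e.day), e.concept, e.setting))
        for r in sorted(rec.prescriptions, key=lambda r: (r.day, r.drug_concept)):
            rxs.append((pid, format_day(r.day), r.drug_concept, r.n_issues))
        for c in sorted(rec.covariates, key=lambda c: (c.day, c.kind)):
            covs.append((pid, format_day(c.day), c.kind, c.value))
    pd.DataFrame(pats, columns=_PATIENT_COLS).to_csv(
        directory / "patients.csv", index=False
    )
    pd.DataFrame(enr, columns=_ENROLL_COLS).to_csv(
        directory / "enrollment.csv", index=False
    )
    pd.DataFrame(evs, columns=_EVENT_COLS).to_csv(
        directory / "events.csv", index=False
    )
    pd.DataFrame(rxs, columns=_RX_COLS).to_csv(
        directory / "prescriptions.csv", index=False
    )
    if covs:
        pd.DataFrame(covs, columns=_COV_COLS).to_csv(
            directory / "covariates.csv", index=False
        )
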