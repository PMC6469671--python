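"""Shared fixtures: the packaged codelist and a tiny-record factory."""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pytest

from msphen.codelist import default_codelist
from msphen.records import (
    CodedEvent,
    CovariateObs,
    Dialect,
    EnrollmentPeriod,
    Patient,
    PatientRecord,
    Prescription,
)

#: a fixed reference day (2010-01-01) for hand-built records
D0 = dt.date(2010, 1, 1).toordinal()

FIXTURE_BUNDLE = Path(__file__).parent / "data" / "fixture_bundle"


@pytest.fixture(scope="session")
def codelist():
    return default_codelist()


@pytest.fixture
def rec():
    """Factory for small hand-built patient records.

    Days are offsets from ``D0``; ``ms_days``/``dem_days`` place MS and
    demyelinating diagnosis events, ``dmt_days`` DMT prescriptions,
    ``events`` arbitrary ``(day, concept[, setting])`` tuples and ``rx``
    ``(day, concept[, n_issues])`` tuples.
    """

    def _make(
        dialect: str = "dod",
        ms_days=(),
        dem_days=(),
        dmt_days=(),
        events=(),
        rx=(),
        enroll=None,
        birth_offset=-30 * 365,
        sex="F",
        geo="G1",
        pid="T1",
        covs=(),
    ) -> PatientRecord:
        dia = Dialect.CLAIMS_DOD if dialect == "dod" else Dialect.EMR_CPRD
        patient = Patient(pid, sex, D0 + birth_offset, geo, dia)
        if enroll is None:
            enroll = [(-4000, 4000)]
        periods = [EnrollmentPeriod(D0 + a, D0 + b) for a, b in enroll]
        evs = [CodedEvent(D0 + d, "ms") for d in ms_days]
        evs += [CodedEvent(D0 + d, "demyelinating_disease") for d in dem_days]
        for tup in events:
            day, concept, *rest = tup
            evs.append(CodedEvent(D0 + day, concept, rest[0] if rest else "outpatient"))
        rxs = [Prescription(D0 + d, "interferon_beta") for d in dmt_days]
        for tup in rx:
            day, concept, *rest = tup
            rxs.append(Prescription(D0 + day, concept, rest[0] if rest else 1))
        cov = [CovariateObs(D0 + d, kind, value) for d, kind, value in covs]
        return PatientRecord(patient, periods, evs, rxs, cov)

    return _make
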