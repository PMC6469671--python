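"""Record model, bundle I/O and timeline-query primitives."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msphen.records import (
    Bundle,
    DataError,
    EnrollmentPeriod,
    SchemaError,
    count_distinct_dates,
    first_date_of,
    count_rx,
    merge_periods,
    periods_cover,
    read_bundle,
    write_bundle,
)
from conftest import D0, FIXTURE_BUNDLE


def _ms_record(days):
    """Plain builder (no fixtures) for hypothesis-driven property tests."""
    from msphen.records import CodedEvent, Dialect, EnrollmentPeriod, Patient, PatientRecord

    return PatientRecord(
        Patient("H1", "F", D0 - 20000, "G1", Dialect.CLAIMS_DOD),
        [EnrollmentPeriod(D0 - 4000, D0 + 4000)],
        [CodedEvent(D0 + d, "ms") for d in days],
        [],
    )


class TestBundleIO:
    def test_fixture_bundle_event_counts(self, codelist):
        """The hand-authored 5-patient bundle loads with known row counts."""
        bundle = read_bundle(FIXTURE_BUNDLE, codelist)
        assert len(bundle) == 5
        counts = {pid: len(r.events) for pid, r in bundle.records.items()}
        assert counts == {"F001": 5, "F002": 1, "F003": 5, "F004": 0, "F005": 1}
        assert len(bundle["F001"].prescriptions) == 2
        # contiguous enrollment periods are merged at load
        assert len(bundle["F002"].enrollment) == 1
        assert bundle["F004"].covariates[0].value == "current"

    def test_round_trip_identity(self, codelist, tmp_path):
        bundle = read_bundle(FIXTURE_BUNDLE, codelist)
        write_bundle(bundle, tmp_path / "a")
        again = read_bundle(tmp_path / "a", codelist)
        write_bundle(again, tmp_path / "b")
        for name in ("patients", "enrollment", "events", "prescriptions", "covariates"):
            a = (tmp_path / "a" / f"{name}.csv").read_bytes()
            b = (tmp_path / "b" / f"{name}.csv").read_bytes()
            assert a == b, name

    def test_empty_events_file(self, codelist, tmp_path):
        for f in ("patients", "enrollment", "events", "prescriptions"):
            src = (FIXTURE_BUNDLE / f"{f}.csv").read_text()
            if f in ("events", "prescriptions"):
                src = src.splitlines()[0] + "\n"
            (tmp_path / f"{f}.csv").write_text(src)
        bundle = read_bundle(tmp_path, codelist)
        assert len(bundle) == 5
        assert all(not r.events for r in bundle)

    def test_missing_column_names_column(self, codelist, tmp_path):
        lines = (FIXTURE_BUNDLE / "patients.csv").read_text().splitlines()
        without_geo = [",".join(x.split(",")[:3] + x.split(",")[4:]) for x in lines]
        (tmp_path / "patients.csv").write_text("\n".join(without_geo) + "\n")
        for f in ("enrollment", "events", "prescriptions"):
            (tmp_path / f"{f}.csv").write_text((FIXTURE_BUNDLE / f"{f}.csv").read_text())
        with pytest.raises(SchemaError, match="geography"):
            read_bundle(tmp_path, codelist)

    def test_bad_date_reports_line_number(self, codelist, tmp_path):
        for f in ("patients", "enrollment", "events", "prescriptions"):
            (tmp_path / f"{f}.csv").write_text((FIXTURE_BUNDLE / f"{f}.csv").read_text())
        text = (tmp_path / "events.csv").read_text().replace("2008-06-10", "notadate")
        (tmp_path / "events.csv").write_text(text)
        with pytest.raises(DataError, match=r"events\.csv line 4"):
            read_bundle(tmp_path, codelist)

    def test_duplicate_patient_id_fatal(self, codelist, tmp_path):
        for f in ("patients", "enrollment", "events", "prescriptions"):
            (tmp_path / f"{f}.csv").write_text((FIXTURE_BUNDLE / f"{f}.csv").read_text())
        with open(tmp_path / "patients.csv", "a") as fh:
            fh.write("F001,F,1970-01-15,G001,CLAIMS_DOD\n")
        with pytest.raises(DataError, match="duplicate"):
            read_bundle(tmp_path, codelist)

    def test_unknown_concepts_reported(self, codelist, tmp_path):
        for f in ("patients", "enrollment", "events", "prescriptions"):
            (tmp_path / f"{f}.csv").write_text((FIXTURE_BUNDLE / f"{f}.csv").read_text())
        with open(tmp_path / "events.csv", "a") as fh:
            fh.write("F001,2009-02-02,made_up_concept,outpatient\n")
        bundle = read_bundle(tmp_path, codelist)
        assert bundle.unknown_concepts == {"made_up_concept"}


class TestTimelineQueries:
    def test_same_day_codes_count_once(self, codelist, rec):
        r = rec(ms_days=[100, 100, 100])
        assert count_distinct_dates(r, codelist, "ms_diagnosis") == 1

    def test_absent_category_counts_zero(self, codelist, rec):
        assert count_distinct_dates(rec(), codelist, "ms_diagnosis") == 0

    def test_window_restricts_distinct_dates(self, codelist, rec):
        # 12 events on 7 distinct days 0..6; window covering days 1..5 -> 5
        days = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 6]
        r = rec(ms_days=days)
        n = count_distinct_dates(
            r, codelist, "ms_diagnosis", window=(D0 + 1, D0 + 5)
        )
        assert n == 5

    def test_unknown_category_raises(self, codelist, rec):
        from msphen.records import ConfigError

        with pytest.raises(ConfigError):
            count_distinct_dates(rec(), codelist, "no_such_category")

    def test_first_date_is_earliest(self, codelist, rec):
        r = rec(ms_days=[200, 150])
        assert first_date_of(r, codelist, "ms_diagnosis") == D0 + 150
        assert first_date_of(rec(), codelist, "ms_diagnosis") is None
        r2 = rec(ms_days=[150, 150, 200])
        assert first_date_of(r2, codelist, "ms_diagnosis") == D0 + 150

    def test_rx_count_sums_issues(self, codelist, rec):
        r = rec(rx=[(0, "interferon_beta", 2), (10, "glatiramer", 1)])
        assert count_rx(r, codelist, "dmt_or_dalfampridine") == 3

    def test_dialect_inactive_concept_ignored(self, codelist, rec):
        # overdose has no claims-dialect codes, so it is invisible there
        dod = rec(dialect="dod", events=[(0, "overdose")])
        cprd = rec(dialect="cprd", events=[(0, "overdose")])
        assert count_distinct_dates(dod, codelist, "suicidal_behavior") == 0
        assert count_distinct_dates(cprd, codelist, "suicidal_behavior") == 1

    @settings(max_examples=100, derandomize=True)
    @given(days=st.lists(st.integers(0, 60), max_size=25), extra=st.integers(0, 60))
    def test_distinct_dates_monotone_and_duplication_invariant(
        self, codelist, days, extra
    ):
        base = count_distinct_dates(_ms_record(days), codelist, "ms_diagnosis")
        grown = count_distinct_dates(
            _ms_record(days + [extra]), codelist, "ms_diagnosis"
        )
        assert grown >= base
        if days:
            dup = count_distinct_dates(
                _ms_record(days + [days[0]]), codelist, "ms_diagnosis"
            )
            assert dup == base

    @settings(max_examples=60, derandomize=True)
    @given(days=st.lists(st.integers(-500, 500), min_size=1, max_size=20))
    def test_first_date_lower_bounds_all_events(self, codelist, days):
        r = _ms_record(days)
        first = first_date_of(r, codelist, "ms_diagnosis")
        assert all(first <= D0 + d for d in days)


class TestEnrollment:
    def test_overlapping_periods_merge(self):
        merged = merge_periods(
            [EnrollmentPeriod(0, 100), EnrollmentPeriod(50, 200), EnrollmentPeriod(300, 400)]
        )
        assert merged == [EnrollmentPeriod(0, 200), EnrollmentPeriod(300, 400)]

    def test_coverage_requires_single_period(self):
        periods = [EnrollmentPeriod(0, 100), EnrollmentPeriod(150, 400)]
        assert periods_cover(periods, 160, 300)
        assert not periods_cover(periods, 50, 200)  # gap inside the interval
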