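"""Tiered case algorithms, exclusion rules and the incident filter."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msphen.classify import (
    ExclusionReason,
    Tier,
    apply_exclusions,
    build_ms_cohort,
    classify_cprd,
    classify_dod,
    incident_filter,
)
from msphen.records import Bundle, Dialect, DialectError
from conftest import D0


class TestClaimsAlgorithm:
    def test_heavy_coder_is_probable(self, codelist, rec):
        # the typical claims case: ~45 diagnosis dates, ~30 DMT scripts
        r = rec(ms_days=range(0, 450, 10), dmt_days=range(0, 300, 10))
        cls = classify_dod(r, codelist)
        assert cls.tier == Tier.PROBABLE
        assert cls.n_ms_dx_dates == 45
        assert cls.n_dmt_rx == 30

    def test_gate_requires_a_dmt(self, codelist, rec):
        r = rec(ms_days=range(8))
        assert classify_dod(r, codelist).tier == Tier.NON_CASE

    def test_empty_record_is_non_case(self, codelist, rec):
        assert classify_dod(rec(), codelist).tier == Tier.NON_CASE

    def test_demyelinating_only_tier(self, codelist, rec):
        r = rec(dem_days=[0, 50], dmt_days=[10])
        assert classify_dod(r, codelist).tier == Tier.POSSIBLE_DEMYELINATING_ONLY

    def test_low_count_tier(self, codelist, rec):
        r = rec(ms_days=[0, 30, 60], dmt_days=[5, 10])
        assert classify_dod(r, codelist).tier == Tier.POSSIBLE_LOW_COUNT

    def test_probable_takes_precedence_at_boundary(self, codelist, rec):
        # 10 dx dates + 5 rx satisfies both the probable and low-count rules
        r = rec(ms_days=range(0, 100, 10), dmt_days=range(5))
        assert classify_dod(r, codelist).tier == Tier.PROBABLE

    def test_wrong_dialect_raises(self, codelist, rec):
        with pytest.raises(DialectError):
            classify_dod(rec(dialect="cprd"), codelist)
        with pytest.raises(DialectError):
            classify_cprd(rec(dialect="dod"), codelist)

    @settings(max_examples=80, derandomize=True)
    @given(
        n_ms=st.integers(0, 14),
        n_rx=st.integers(0, 14),
        extra_day=st.integers(500, 900),
    )
    def test_adding_evidence_never_demotes_probable(
        self, codelist, n_ms, n_rx, extra_day
    ):
        from conftest import D0 as _D0
        from msphen.records import CodedEvent, EnrollmentPeriod, Patient, PatientRecord, Prescription

        def build(ms, rx, extra_ms=False, extra_rx=False):
            evs = [CodedEvent(_D0 + 10 * i, "ms") for i in range(ms)]
            if extra_ms:
                evs.append(CodedEvent(_D0 + extra_day, "ms"))
            rxs = [Prescription(_D0 + i, "interferon_beta") for i in range(rx)]
            if extra_rx:
                rxs.append(Prescription(_D0 + extra_day, "glatiramer"))
            return PatientRecord(
                Patient("H", "F", _D0 - 20000, "G1", Dialect.CLAIMS_DOD),
                [EnrollmentPeriod(_D0 - 4000, _D0 + 4000)],
                evs,
                rxs,
            )

        base = classify_dod(build(n_ms, n_rx), codelist)
        if base.tier == Tier.PROBABLE:
            assert classify_dod(build(n_ms, n_rx, extra_ms=True), codelist).tier == Tier.PROBABLE
            assert classify_dod(build(n_ms, n_rx, extra_rx=True), codelist).tier == Tier.PROBABLE


class TestEmrAlgorithm:
    def test_two_dates_plus_symptom_is_probable(self, codelist, rec):
        r = rec(dialect="cprd", ms_days=[0, 40], events=[(-100, "skin_sensation_disturbance")])
        assert classify_cprd(r, codelist).tier == Tier.PROBABLE

    def test_single_code_no_support_is_unlikely(self, codelist, rec):
        r = rec(dialect="cprd", ms_days=[0])
        assert classify_cprd(r, codelist).tier == Tier.UNLIKELY

    def test_no_ms_codes_is_non_case(self, codelist, rec):
        r = rec(dialect="cprd", events=[(0, "dizziness")])
        assert classify_cprd(r, codelist).tier == Tier.NON_CASE

    def test_same_date_codes_count_as_one(self, codelist, rec):
        # two MS codes on one date, no support: a single distinct date -> unlikely
        r = rec(dialect="cprd", ms_days=[0, 0])
        assert classify_cprd(r, codelist).tier == Tier.UNLIKELY

    def test_one_code_with_support_is_possible(self, codelist, rec):
        r = rec(dialect="cprd", ms_days=[0], events=[(10, "optic_neuritis")])
        assert classify_cprd(r, codelist).tier == Tier.POSSIBLE_CPRD_SUPPORTED

    def test_two_dates_no_support_is_possible_unsupported(self, codelist, rec):
        r = rec(dialect="cprd", ms_days=[0, 40])
        assert classify_cprd(r, codelist).tier == Tier.POSSIBLE_CPRD_UNSUPPORTED

    def test_symptomatic_treatment_rx_counts_as_support(self, codelist, rec):
        r = rec(dialect="cprd", ms_days=[0, 40], rx=[(-30, "oxybutynin")])
        assert classify_cprd(r, codelist).tier == Tier.PROBABLE


class TestExclusions:
    def test_als_excludes_at_any_time(self, codelist, rec):
        r = rec(ms_days=range(0, 450, 10), dmt_days=range(10),
                events=[(-3650, "als")])
        cls = apply_exclusions(r, classify_dod(r, codelist), codelist)
        assert cls.excluded
        assert cls.exclusion_reason == ExclusionReason.ALS_ANY_TIME

    def test_stroke_soon_after_single_emr_code(self, codelist, rec):
        r = rec(dialect="cprd", ms_days=[0], events=[(90, "stroke")])
        cls = apply_exclusions(r, classify_cprd(r, codelist), codelist)
        assert cls.excluded
        assert cls.exclusion_reason == ExclusionReason.STROKE_TIA_NEAR_MS

    def test_stroke_beyond_six_months_does_not_exclude(self, codelist, rec):
        r = rec(dialect="cprd", ms_days=[0], events=[(184, "stroke")])
        cls = apply_exclusions(r, classify_cprd(r, codelist), codelist)
        assert not cls.excluded

    def test_enough_claims_codes_override_tia(self, codelist, rec):
        # six distinct MS dates in the claims dialect: the few-codes
        # condition fails, so a prior TIA does not exclude
        r = rec(ms_days=range(0, 60, 10), dmt_days=range(5), events=[(-500, "tia")])
        cls = apply_exclusions(r, classify_dod(r, codelist), codelist)
        assert not cls.excluded

    def test_alternate_dx_with_few_codes(self, codelist, rec):
        r = rec(ms_days=[0, 10], dmt_days=[0], events=[(-200, "alternate_diagnosis")])
        cls = apply_exclusions(r, classify_dod(r, codelist), codelist)
        assert cls.excluded
        assert cls.exclusion_reason == ExclusionReason.ALTERNATE_DX_FEW_MS_CODES

    def test_clean_record_not_excluded(self, codelist, rec):
        r = rec(ms_days=[0], dmt_days=[0])
        assert not apply_exclusions(r, classify_dod(r, codelist), codelist).excluded


class TestIncidentFilter:
    def test_short_lookback_is_prevalent(self, codelist, rec):
        r = rec(ms_days=[0], dmt_days=[0], enroll=[(-100, 1000)])
        cls = incident_filter(r, classify_dod(r, codelist))
        assert not cls.incident

    def test_exactly_one_year_is_incident(self, codelist, rec):
        r = rec(ms_days=[0], dmt_days=[0], enroll=[(-365, 1000)])
        assert incident_filter(r, classify_dod(r, codelist)).incident

    def test_gap_inside_lookback_year(self, codelist, rec):
        r = rec(ms_days=[0], dmt_days=[0], enroll=[(-800, -200), (-150, 1000)])
        assert not incident_filter(r, classify_dod(r, codelist)).incident


class TestCohortAssembly:
    def test_population_without_ms_codes_is_empty(self, codelist, rec):
        recs = {f"P{i}": rec(pid=f"P{i}", events=[(0, "dizziness")]) for i in range(5)}
        cohort = build_ms_cohort(Bundle(recs, Dialect.CLAIMS_DOD), codelist)
        assert cohort.members == []

    def test_members_have_ms_or_demyelinating_evidence(self, codelist, rec):
        recs = {
            "A": rec(pid="A", ms_days=range(0, 120, 10), dmt_days=range(6)),
            "B": rec(pid="B"),
            "C": rec(pid="C", dem_days=[0], dmt_days=[1]),
        }
        cohort = build_ms_cohort(Bundle(recs, Dialect.CLAIMS_DOD), codelist)
        ids = cohort.member_ids
        assert set(ids) == {"A", "C"}
        for m in cohort.members:
            assert m.n_ms_dx_dates + m.n_demyelinating_dx_dates >= 1
            assert m.first_ms_date is not None

    def test_classification_is_order_independent(self, codelist, rec):
        base = rec(ms_days=[5, 60, 200], dmt_days=[10, 20], events=[(1, "dizziness")])
        shuffled_events = list(base.events)
        random.Random(3).shuffle(shuffled_events)
        shuffled = rec(pid="T1")
        shuffled.events = shuffled_events
        shuffled.prescriptions = list(reversed(base.prescriptions))
        assert classify_dod(base, codelist) == classify_dod(shuffled, codelist)
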