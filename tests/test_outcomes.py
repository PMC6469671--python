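"""Outcome ascertainment rules at the index date."""

from __future__ import annotations

import numpy as np
import pytest

from msphen.outcomes import (
    acute_window_present,
    anytime_present,
    attribute_anticonvulsants,
    cancer_present,
    categorize_covariates,
    chronic_present,
    hospitalized_infection_present,
    medication_use,
    meningitis_dod_present,
    suicidal_present,
    treated_pair_present,
)
from msphen.records import DataError
from conftest import D0

IDX = D0  # index date for all tests

SITES = ("infection:urinary", "infection:respiratory", "infection:pneumonia_influenza")


class TestChronicRule:
    def test_single_emr_code_years_before(self, codelist, rec):
        r = rec(dialect="cprd", events=[(-5 * 365, "epilepsy")])
        assert chronic_present(r, codelist, "comorbidity:epilepsy", IDX)

    def test_four_claims_codes_insufficient(self, codelist, rec):
        r = rec(events=[(-d, "epilepsy") for d in (10, 20, 30, 40)])
        assert not chronic_present(r, codelist, "comorbidity:epilepsy", IDX)

    def test_fifth_code_on_entry_date_counts(self, codelist, rec):
        r = rec(events=[(-d, "epilepsy") for d in (10, 20, 30, 40)] + [(0, "epilepsy")])
        assert chronic_present(r, codelist, "comorbidity:epilepsy", IDX)

    def test_codes_after_index_never_count(self, codelist, rec):
        r = rec(events=[(d, "epilepsy") for d in (1, 2, 3, 4, 5)])
        assert not chronic_present(r, codelist, "comorbidity:epilepsy", IDX)

    def test_claims_positive_implies_emr_positive(self, codelist, rec):
        # dialect threshold ordering: >=5 dates subsumes >=1
        days = [(-d, "epilepsy") for d in (10, 20, 30, 40, 50)]
        dod = rec(dialect="dod", events=days)
        cprd = rec(dialect="cprd", events=days)
        assert chronic_present(dod, codelist, "comorbidity:epilepsy", IDX)
        assert chronic_present(cprd, codelist, "comorbidity:epilepsy", IDX)


class TestTreatedPair:
    def test_rx_90_days_after_dx(self, codelist, rec):
        r = rec(events=[(-90, "depression")], rx=[(0, "antidepressant")])
        assert treated_pair_present(
            r, codelist, "comorbidity:depression", "medication:antidepressants", IDX
        )

    def test_rx_91_days_after_dx_fails(self, codelist, rec):
        r = rec(events=[(-91, "depression")], rx=[(0, "antidepressant")])
        assert not treated_pair_present(
            r, codelist, "comorbidity:depression", "medication:antidepressants", IDX
        )

    def test_rx_before_dx_is_symmetric(self, codelist, rec):
        r = rec(events=[(-10, "depression")], rx=[(-40, "antidepressant")])
        assert treated_pair_present(
            r, codelist, "comorbidity:depression", "medication:antidepressants", IDX
        )


class TestCancer:
    def test_claims_five_codes_within_six_months(self, codelist, rec):
        r = rec(events=[(-d, "cancer") for d in (0, 30, 60, 90, 120)])
        assert cancer_present(r, codelist, IDX)

    def test_claims_spread_codes_do_not_qualify(self, codelist, rec):
        # 9 codes each 200 days apart: no 5 within 183 days, total < 10
        r = rec(events=[(-200 * i, "cancer") for i in range(9)],
                enroll=[(-2000 - 200 * 9, 100)])
        assert not cancer_present(r, codelist, IDX)

    def test_claims_ten_codes_ever(self, codelist, rec):
        r = rec(events=[(-300 * i - 5, "cancer") for i in range(10)],
                enroll=[(-4000, 100)])
        assert cancer_present(r, codelist, IDX)

    def test_history_code_always_qualifies(self, codelist, rec):
        for dialect in ("dod", "cprd"):
            r = rec(dialect=dialect, events=[(-400, "cancer_history")])
            assert cancer_present(r, codelist, IDX)

    def test_emr_single_code(self, codelist, rec):
        r = rec(dialect="cprd", events=[(-50, "cancer")])
        assert cancer_present(r, codelist, IDX)


class TestAcuteWindow:
    @pytest.mark.parametrize(
        "offset,expected", [(-200, True), (-400, False), (0, True), (-365, True)]
    )
    def test_one_year_lookback_boundaries(self, codelist, rec, offset, expected):
        r = rec(events=[(offset, "urinary_infection")])
        got = acute_window_present(r, codelist, "infection:urinary", IDX)
        assert got == expected


class TestHospitalizedInfection:
    def test_claims_inpatient_event(self, codelist, rec):
        r = rec(events=[(-100, "pneumonia_influenza", "inpatient")])
        assert hospitalized_infection_present(r, codelist, IDX, SITES)

    def test_claims_outpatient_event_fails(self, codelist, rec):
        r = rec(events=[(-100, "pneumonia_influenza", "outpatient")])
        assert not hospitalized_infection_present(r, codelist, IDX, SITES)

    def test_emr_marker_within_one_week(self, codelist, rec):
        r = rec(dialect="cprd",
                events=[(-100, "urinary_infection"), (-95, "hospital_admission")])
        assert hospitalized_infection_present(r, codelist, IDX, SITES)

    def test_emr_marker_ten_days_later_fails(self, codelist, rec):
        r = rec(dialect="cprd",
                events=[(-100, "urinary_infection"), (-90, "hospital_admission")])
        assert not hospitalized_infection_present(r, codelist, IDX, SITES)


class TestMeningitisClaimsRule:
    def test_two_codes_plus_antibiotic(self, codelist, rec):
        r = rec(events=[(-50, "meningitis"), (-40, "meningitis")],
                rx=[(-45, "antibiotic")])
        assert meningitis_dod_present(r, codelist, IDX)

    def test_one_code_only_fails(self, codelist, rec):
        r = rec(events=[(-50, "meningitis")], rx=[(-45, "antibiotic")])
        assert not meningitis_dod_present(r, codelist, IDX)

    def test_no_codes(self, codelist, rec):
        assert not meningitis_dod_present(rec(), codelist, IDX)


class TestSuicidal:
    def test_single_self_harm_code(self, codelist, rec):
        assert suicidal_present(rec(events=[(-700, "self_harm")]), codelist, IDX)

    def test_absent(self, codelist, rec):
        assert not suicidal_present(rec(), codelist, IDX)

    def test_overdose_inactive_in_claims_dialect(self, codelist, rec):
        dod = rec(dialect="dod", events=[(-10, "overdose")])
        cprd = rec(dialect="cprd", events=[(-10, "overdose")])
        assert not suicidal_present(dod, codelist, IDX)
        assert suicidal_present(cprd, codelist, IDX)


class TestMedications:
    def test_counts_in_window(self, codelist, rec):
        r = rec(rx=[(-10, "opioid"), (-100, "opioid"), (-300, "opioid")])
        assert medication_use(r, codelist, "medication:opioids", IDX) == (True, 3)

    def test_window_boundary(self, codelist, rec):
        r = rec(rx=[(-366, "opioid")])
        assert medication_use(r, codelist, "medication:opioids", IDX) == (False, 0)

    def test_anticonvulsant_attribution(self, codelist, rec):
        with_epi = rec(rx=[(-30, "anticonvulsant")],
                       events=[(-2 * 365, "epilepsy")])
        without = rec(rx=[(-30, "anticonvulsant")])
        none = rec()
        assert attribute_anticonvulsants(with_epi, codelist, IDX) == "epilepsy_treatment"
        assert attribute_anticonvulsants(without, codelist, IDX) == "ms_symptom_treatment"
        assert attribute_anticonvulsants(none, codelist, IDX) == "none"


class TestCovariates:
    def test_bmi_band_boundaries(self, rec):
        for value, band in ((24.9, "18.5-25"), (30.0, "30+"), (18.4, "<18.5"),
                            (25.0, "25-30")):
            r = rec(covs=[(-100, "bmi", value)])
            assert categorize_covariates(r, IDX)["bmi_band"] == band

    def test_missing_is_unknown(self, rec):
        out = categorize_covariates(rec(), IDX)
        assert out == {"smoking": "unknown", "bmi_band": "unknown"}

    def test_most_recent_observation_wins(self, rec):
        r = rec(covs=[(-500, "smoking", "never"), (-100, "smoking", "current")])
        assert categorize_covariates(r, IDX)["smoking"] == "current"

    def test_non_positive_bmi_is_a_data_error(self, rec):
        with pytest.raises(DataError):
            categorize_covariates(rec(covs=[(-10, "bmi", -1.0)]), IDX)


class TestRuleEngineAgainstNaiveScan:
    def test_random_small_records_match_naive_oracle(self, codelist, rec):
        """Window rules agree with an independent brute-force event scan."""
        rng = np.random.default_rng(42)
        concepts = ["epilepsy", "urinary_infection", "depression", "self_harm"]
        for _ in range(300):
            events = [
                (int(rng.integers(-800, 200)), concepts[int(rng.integers(4))])
                for _ in range(int(rng.integers(0, 12)))
            ]
            rxs = [
                (int(rng.integers(-800, 200)), "antidepressant")
                for _ in range(int(rng.integers(0, 4)))
            ]
            dialect = "dod" if rng.random() < 0.5 else "cprd"
            r = rec(dialect=dialect, events=events, rx=rxs)

            # naive re-derivations from the raw tuples
            epi_dates = {d for d, c in events if c == "epilepsy" and d <= 0}
            want_chronic = len(epi_dates) >= (5 if dialect == "dod" else 1)
            assert chronic_present(r, codelist, "comorbidity:epilepsy", IDX) == want_chronic

            want_acute = any(
                c == "urinary_infection" and -365 <= d <= 0 for d, c in events
            )
            assert acute_window_present(r, codelist, "infection:urinary", IDX) == want_acute

            want_pair = any(
                c == "depression" and d <= 0 and abs(d - rd) <= 90
                for d, c in events
                for rd, _ in rxs
                if rd <= 0
            )
            got_pair = treated_pair_present(
                r, codelist, "comorbidity:depression",
                "medication:antidepressants", IDX,
            )
            assert got_pair == want_pair

    def test_window_monotonicity(self, codelist, rec):
        """Enlarging a look-back window never turns presence into absence."""
        r = rec(events=[(-500, "urinary_infection")])
        for w1, w2 in ((365, 500), (500, 700)):
            p1 = acute_window_present(r, codelist, "infection:urinary", IDX, w1)
            p2 = acute_window_present(r, codelist, "infection:urinary", IDX, w2)
            assert p2 >= p1
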