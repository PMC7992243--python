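"""Gate-by-gate behaviour of the Berlin screen, plus cohort-level properties."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ardscreen import ScreenConfig, Severity, grade_severity, screen_cohort, screen_patient
from ardscreen.ehr_model import (
    BloodGasResult,
    CardiacEvent,
    CardiacCategory,
    ComorbidityCategory,
    ComorbidityEntry,
    EcgReport,
    IcuStay,
    ImagingReport,
    Modality,
    PatientRecord,
    RiskFactorCategory,
    RiskFactorEvent,
    RiskFactorSource,
    UnitClass,
    VentRecord,
    VitalFio2,
)
from ardscreen.errors import ContractError
from ardscreen.screen import (
    ExclusionReason,
    build_pf_measurements,
    cardiogenic_excluded,
    check_eligibility,
    fibrosis_excluded,
    find_risk_factors,
    find_time_zero,
    funnel_counts,
    invasive_vent_duration,
    positive_cxr_near,
    qualifying_pf,
    radiology_positive,
)

from conftest import T, build_store, full_positive_rows


def _stay(admit="2016-06-01T00:00", disch="2016-06-10T00:00", unit=UnitClass.icu):
    return IcuStay("P1", T(admit), T(disch), unit)


def _vent(ts, peep, loc=UnitClass.icu, mode="AC/VC", invasive=True):
    return VentRecord("P1", T(ts), peep, mode, invasive, loc)


class TestEligibility:
    def test_adult_with_authorization_is_eligible(self):
        p = PatientRecord("P1", datetime.date(1976, 1, 1), True)
        ok, reason = check_eligibility(p, _stay())
        assert ok and reason is None

    def test_no_authorization_excludes(self):
        p = PatientRecord("P1", datetime.date(1976, 1, 1), False)
        ok, reason = check_eligibility(p, _stay())
        assert not ok and reason is ExclusionReason.no_authorization

    def test_seventeen_year_old_excluded(self):
        p = PatientRecord("P1", datetime.date(1999, 1, 1), True)  # 17 at 2016-06 admit
        ok, reason = check_eligibility(p, _stay())
        assert not ok and reason is ExclusionReason.under_18

    def test_eighteenth_birthday_on_admit_is_eligible(self):
        p = PatientRecord("P1", datetime.date(1998, 6, 1), True)
        ok, _ = check_eligibility(p, _stay())
        assert ok

    def test_missing_birth_date_ineligible(self):
        p = PatientRecord("P1", None, True)
        ok, reason = check_eligibility(p, _stay())
        assert not ok and reason is ExclusionReason.under_18


class TestTimeZero:
    def test_first_record_meeting_threshold(self, cfg):
        vents = [_vent("2016-06-01T10:00", 4), _vent("2016-06-01T11:00", 5)]
        tz, mode, stay = find_time_zero(vents, [_stay()], cfg)
        assert tz == T("2016-06-01T11:00") and mode == "AC/VC"
        assert stay.unit_class is UnitClass.icu

    def test_procedural_area_record_ignored(self, cfg):
        vents = [_vent("2016-06-01T10:00", 8, loc=UnitClass.procedural_area)]
        tz, mode, stay = find_time_zero(vents, [_stay()], cfg)
        assert tz is None

    def test_no_records_yields_none(self, cfg):
        # home BiPAP patient: nothing charted
        assert find_time_zero([], [_stay()], cfg) == (None, None, None)

    def test_record_outside_any_icu_stay_ignored(self, cfg):
        vents = [_vent("2016-07-15T10:00", 8)]
        assert find_time_zero(vents, [_stay()], cfg)[0] is None

    def test_empty_mode_borrows_nearest_icu_mode(self, cfg):
        vents = [
            _vent("2016-06-01T10:00", 8, mode=""),
            _vent("2016-06-01T10:30", 8, mode="SIMV"),
            _vent("2016-06-01T13:00", 8, mode="PRVC"),
        ]
        tz, mode, _ = find_time_zero(vents, [_stay()], cfg)
        assert tz == T("2016-06-01T10:00") and mode == "SIMV"


def _gas(ts, pao2, fio2=None):
    return BloodGasResult("P1", T(ts), pao2, fio2)


class TestPFMeasurements:
    def test_lab_fio2_direct_division(self, cfg):
        pfs = build_pf_measurements([_gas("2016-06-01T12:00", 80, 0.8)], [], cfg)
        assert len(pfs) == 1
        assert pfs[0].ratio == pytest.approx(100.0)
        assert pfs[0].fio2_source == "lab"

    def test_nearest_vitals_within_window(self, cfg):
        vitals = [
            VitalFio2("P1", T("2016-06-01T12:10"), 0.50),
            VitalFio2("P1", T("2016-06-01T12:20"), 0.60),
        ]
        pfs = build_pf_measurements([_gas("2016-06-01T12:00", 60)], vitals, cfg)
        assert len(pfs) == 1
        assert pfs[0].fio2 == pytest.approx(0.50)
        assert pfs[0].ratio == pytest.approx(120.0)
        assert pfs[0].fio2_source == "vitals"

    def test_vitals_outside_window_yield_no_measurement(self, cfg):
        vitals = [VitalFio2("P1", T("2016-06-01T12:20"), 0.50)]
        assert build_pf_measurements([_gas("2016-06-01T12:00", 60)], vitals, cfg) == []

    def test_equidistant_tie_goes_to_earlier_record(self, cfg):
        vitals = [
            VitalFio2("P1", T("2016-06-01T11:50"), 0.40),
            VitalFio2("P1", T("2016-06-01T12:10"), 0.80),
        ]
        pfs = build_pf_measurements([_gas("2016-06-01T12:00", 60)], vitals, cfg)
        assert pfs[0].fio2 == pytest.approx(0.40)


class TestQualifyingPF:
    def _pfs(self, cfg, specs):
        gases = [_gas(ts, ratio * 0.5, 0.5) for ts, ratio in specs]
        return build_pf_measurements(gases, [], cfg)

    def test_minimum_qualifying_ratio_wins(self, cfg):
        pfs = self._pfs(cfg, [("2016-06-01T12:00", 250), ("2016-06-01T14:00", 180),
                              ("2016-06-01T16:00", 320)])
        q = qualifying_pf(pfs, T("2016-06-01T10:00"), cfg)
        assert q.ratio == pytest.approx(180.0)

    def test_all_ratios_above_threshold(self, cfg):
        pfs = self._pfs(cfg, [("2016-06-01T12:00", 310), ("2016-06-01T14:00", 450)])
        assert qualifying_pf(pfs, T("2016-06-01T10:00"), cfg) is None

    def test_no_measurements_at_all(self, cfg):
        assert qualifying_pf([], T("2016-06-01T10:00"), cfg) is None

    def test_measurements_before_time_zero_ignored(self, cfg):
        pfs = self._pfs(cfg, [("2016-06-01T08:00", 150)])
        assert qualifying_pf(pfs, T("2016-06-01T10:00"), cfg) is None


class TestRadiologyKeywords:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Bilateral opacities consistent with pulmonary edema.", True),
            ("Right lower lobe infiltrate. Left lung clear.", False),
            ("Bilateral pleural effusions.", False),  # effusion not a keyword
            ("Bilateral patchy airspace infiltrates.", True),  # 3-token proximity
            ("Bilateral diffuse patchy hazy infiltrates.", False),  # 4 tokens away
            ("Infiltrates bilateral.", False),  # keyword precedes 'bilateral'
            ("Opacities were seen. They are bilateral.", False),  # cross-sentence
            ("BILATERAL EDEMA.", True),  # case-insensitive
            ("", False),
        ],
    )
    def test_bilateral_keyword_pairing(self, text, expected):
        report = ImagingReport("P1", T("2016-06-01T12:00"), Modality.chest_xray, text)
        assert radiology_positive(report) is expected

    def test_window_gating(self, cfg):
        tz = T("2016-06-01T10:00")
        pos = "Bilateral infiltrates."
        neg = "Left lung clear."

        def rpt(ts, text):
            return ImagingReport("P1", T(ts), Modality.chest_xray, text)

        assert positive_cxr_near([rpt("2016-06-01T16:00", pos)], tz, cfg)
        assert not positive_cxr_near([rpt("2016-06-02T06:00", pos)], tz, cfg)  # +20 h
        assert not positive_cxr_near(
            [rpt("2016-06-01T16:00", neg), rpt("2016-06-02T06:00", pos)], tz, cfg
        )
        # a qualifying phrase on a non-chest-film modality does not count
        other = ImagingReport("P1", T("2016-06-01T16:00"), Modality.other, pos)
        assert not positive_cxr_near([other], tz, cfg)


class TestFibrosisGate:
    def test_ipf_entry_excludes(self):
        entries = [ComorbidityEntry("P1", ComorbidityCategory.ipf, T("2015-01-01T00:00"))]
        assert fibrosis_excluded(entries)

    def test_other_charlson_categories_do_not(self):
        entries = [
            ComorbidityEntry("P1", ComorbidityCategory.diabetes, T("2015-01-01T00:00")),
            ComorbidityEntry("P1", ComorbidityCategory.congestive_heart_failure,
                             T("2015-01-01T00:00")),
        ]
        assert not fibrosis_excluded(entries)

    def test_empty_list(self):
        assert not fibrosis_excluded([])


class TestVentDuration:
    def _hourly(self, start, hours, step_min=60):
        t0 = T(start)
        import pandas as pd

        return [
            _vent((t0 + pd.Timedelta(minutes=m)).isoformat(), 8)
            for m in range(0, int(hours * 60) + 1, step_min)
        ]

    def test_eleven_hours_contiguous(self, cfg):
        assert invasive_vent_duration(self._hourly("2016-06-01T08:00", 11), cfg) == pytest.approx(11.0)

    def test_exactly_twelve_hours_passes_boundary(self, cfg):
        dur = invasive_vent_duration(self._hourly("2016-06-01T08:00", 12), cfg)
        assert dur == pytest.approx(12.0)
        assert dur >= cfg.min_vent_duration

    def test_episode_merge_across_half_hour_gap(self, cfg):
        # 08:00-16:00 and 16:30-22:30; the 0.5 h gap merges into one
        # 14.5 h episode (hand-computed)
        vents = self._hourly("2016-06-01T08:00", 8) + self._hourly("2016-06-01T16:30", 6)
        assert invasive_vent_duration(vents, cfg) == pytest.approx(14.5)

    def test_long_gap_splits_episodes(self, cfg):
        # 08:00-12:00 and 18:00-22:00: gap 6 h > merge 1 h -> 4 + 4 h
        vents = self._hourly("2016-06-01T08:00", 4) + self._hourly("2016-06-01T18:00", 4)
        assert invasive_vent_duration(vents, cfg) == pytest.approx(8.0)

    def test_non_invasive_records_do_not_count(self, cfg):
        vents = [_vent("2016-06-01T08:00", 8, invasive=False),
                 _vent("2016-06-01T20:00", 8, invasive=False)]
        assert invasive_vent_duration(vents, cfg) == 0.0

    def test_single_record_is_zero(self, cfg):
        assert invasive_vent_duration([_vent("2016-06-01T08:00", 8)], cfg) == 0.0


class TestRiskFactors:
    def _event(self, ts, cat=RiskFactorCategory.sepsis_septic_shock):
        return RiskFactorEvent("P1", T(ts), cat, RiskFactorSource.diagnosis)

    def test_event_within_window(self, cfg):
        found = find_risk_factors([self._event("2016-06-02T00:00")], T("2016-06-01T00:00"), cfg)
        assert found == {RiskFactorCategory.sepsis_septic_shock}

    def test_late_sepsis_outside_window(self, cfg):
        # onset 80 h after admission: the documented miss mode
        found = find_risk_factors([self._event("2016-06-04T08:00")], T("2016-06-01T00:00"), cfg)
        assert found == set()

    def test_no_events(self, cfg):
        assert find_risk_factors([], T("2016-06-01T00:00"), cfg) == set()


class TestCardiogenicGate:
    def test_adhf_during_stay_excludes(self, cfg):
        ev = CardiacEvent("P1", T("2016-06-03T00:00"), CardiacCategory.adhf_positive)
        excluded, reasons = cardiogenic_excluded([ev], [], _stay(), T("2016-06-01T10:00"), cfg)
        assert excluded and "acute:adhf_positive" in reasons

    def test_acute_event_outside_stay_does_not_exclude(self, cfg):
        ev = CardiacEvent("P1", T("2016-07-03T00:00"), CardiacCategory.cardiogenic_shock)
        excluded, _ = cardiogenic_excluded([ev], [], _stay(), T("2016-06-01T10:00"), cfg)
        assert not excluded

    def test_cad_history_excludes_regardless_of_time(self, cfg):
        ev = CardiacEvent("P1", T("2010-01-01T00:00"), CardiacCategory.cad_history)
        excluded, reasons = cardiogenic_excluded([ev], [], _stay(), T("2016-06-01T10:00"), cfg)
        assert excluded and "history:cad_history" in reasons

    def test_new_lbbb_ecg_within_24h_excludes(self, cfg):
        ecg = EcgReport("P1", T("2016-06-02T06:00"), "Sinus rhythm with new LBBB.")
        excluded, reasons = cardiogenic_excluded([], [ecg], _stay(), T("2016-06-01T10:00"), cfg)
        assert excluded and "ecg:new_st_or_lbbb" in reasons

    def test_lbbb_ecg_outside_24h_does_not_exclude(self, cfg):
        ecg = EcgReport("P1", T("2016-06-02T16:00"), "LBBB noted.")  # +30 h
        excluded, _ = cardiogenic_excluded([], [ecg], _stay(), T("2016-06-01T10:00"), cfg)
        assert not excluded

    def test_benign_ecg_does_not_exclude(self, cfg):
        ecg = EcgReport("P1", T("2016-06-01T12:00"), "Sinus tachycardia. Normal intervals.")
        excluded, _ = cardiogenic_excluded([], [ecg], _stay(), T("2016-06-01T10:00"), cfg)
        assert not excluded


class TestSeverity:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (250, Severity.mild),
            (150, Severity.moderate),
            (99.9, Severity.severe),
            (200, Severity.mild),      # boundary: 200 grades mild
            (100, Severity.moderate),  # boundary: 100 grades moderate
            (300, Severity.mild),
            (0.5, Severity.severe),
        ],
    )
    def test_strata(self, ratio, expected):
        assert grade_severity(ratio) is expected

    @pytest.mark.parametrize("ratio", [0, -5, 300.1, 1000])
    def test_out_of_domain_raises(self, ratio):
        with pytest.raises(ContractError):
            grade_severity(ratio)

    @given(st.floats(min_value=0.01, max_value=300.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partition_total_and_exhaustive(self, ratio):
        assert grade_severity(ratio) in (Severity.mild, Severity.moderate, Severity.severe)


class TestScreenPatient:
    def test_fixture_satisfying_all_gates_is_moderate_ards(self, positive_store):
        r = screen_patient(positive_store, "P1")
        assert r.ards and r.severity is Severity.moderate
        assert r.exclusion_reasons == []
        assert r.time_zero == T("2016-06-01T10:00")
        assert r.qualifying_pf.ratio == pytest.approx(120.0)
        assert all(g.passed for g in r.trace)

    def test_added_ipf_comorbidity_flips_to_fibrosis_exclusion(self):
        rows = full_positive_rows()
        rows["comorbidities"] = [{"patient_id": "P1", "category": "ipf",
                                  "recorded_ts": "2015-01-01T00:00:00+00:00"}]
        r = screen_patient(build_store(**rows), "P1")
        assert not r.ards
        assert r.exclusion_reasons == [ExclusionReason.fibrosis]
        assert r.severity is Severity.none

    def test_no_vent_records_is_no_time_zero(self):
        rows = full_positive_rows()
        rows["vent_settings"] = []
        r = screen_patient(build_store(**rows), "P1")
        assert not r.ards
        assert r.exclusion_reasons == [ExclusionReason.no_time_zero]

    def test_trace_soundness_first_failing_gate_reproduces(self):
        rows = full_positive_rows()
        rows["risk_factors"] = []
        store = build_store(**rows)
        r = screen_patient(store, "P1")
        assert r.exclusion_reasons == [ExclusionReason.no_risk_factor]
        failing = [g for g in r.trace if not g.passed]
        assert len(failing) == 1 and failing[0].name == "risk_factor"
        # re-run the failing gate in isolation
        assert find_risk_factors(
            store.risk_factors_for("P1"), store.icu_stays_for("P1")[0].admit_ts,
            ScreenConfig(),
        ) == set()

    def test_adding_exclusion_row_never_flips_negative_to_positive(self):
        rows = full_positive_rows()
        rows["vent_settings"] = rows["vent_settings"][:8]  # 7 h invasive -> negative
        base = screen_patient(build_store(**rows), "P1")
        assert not base.ards
        rows["cardiac_events"] = [{"patient_id": "P1", "ts": "2016-06-02T00:00:00+00:00",
                                   "category": "chf_history"}]
        again = screen_patient(build_store(**rows), "P1")
        assert not again.ards


class TestCohortProperties:
    def test_widening_windows_never_decreases_positives(self):
        from ardscreen.synthetic import SyntheticCohortSpec, generate_cohort

        spec = SyntheticCohortSpec(
            n_patients=60, ards_prevalence=0.4, seed=21,
            edge_case_rates={"late_sepsis": 0.05, "missing_pf_and_cxr": 0.03},
        )
        store, _ = generate_cohort(spec)
        base_cfg = ScreenConfig()
        base = sum(r.ards for r in screen_cohort(store, base_cfg))
        for update in (
            {"pf_threshold": 300.0},  # unchanged: sanity
            {"fio2_match_window": 45.0},
            {"cxr_window": 48.0},
            {"risk_factor_window": 240.0},
            {"vent_gap_merge": 6.0},
        ):
            widened = sum(r.ards for r in screen_cohort(store, base_cfg.model_copy(update=update)))
            assert widened >= base, update

    def test_funnel_counts_monotone_non_increasing(self):
        from ardscreen.synthetic import SyntheticCohortSpec, generate_cohort

        spec = SyntheticCohortSpec(n_patients=40, ards_prevalence=0.4, seed=8)
        store, _ = generate_cohort(spec)
        counts = funnel_counts(screen_cohort(store))
        values = list(counts.values())
        assert values == sorted(values, reverse=True)

    def test_determinism_byte_identical_results(self, tmp_path):
        from ardscreen import write_results
        from ardscreen.synthetic import SyntheticCohortSpec, generate_cohort

        spec = SyntheticCohortSpec(n_patients=25, ards_prevalence=0.4, seed=13)
        store, _ = generate_cohort(spec)
        for name in ("a.csv", "b.csv"):
            write_results(screen_cohort(store), tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
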