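"""Non-short-circuit reference evaluation of the screen, for oracle checks.

Evaluates every gate independently and declares ARDS iff all pass, without
any of the sequential short-circuiting the production path uses.
"""

from ardscreen.ehr_model import EhrStore, UnitClass
from ardscreen.screen import (
    ScreenConfig,
    build_pf_measurements,
    cardiogenic_excluded,
    check_eligibility,
    fibrosis_excluded,
    find_risk_factors,
    find_time_zero,
    grade_severity,
    invasive_vent_duration,
    qualifying_pf,
)


def reference_screen(store: EhrStore, patient_id: str, cfg: ScreenConfig):
    """Returns (ards, severity-or-None) by evaluating all gates exhaustively."""
    patient = store.patient(patient_id)
    stays = store.icu_stays_for(patient_id)
    vents = store.vents_for(patient_id)
    icu_stays = [s for s in stays if s.unit_class == UnitClass.icu]

    tz, _mode, index_stay = find_time_zero(vents, stays, cfg)
    age_stay = index_stay or (icu_stays[0] if icu_stays else None)

    gates = {"eligibility": check_eligibility(patient, age_stay)[0],
             "time_zero": tz is not None}

    qpf = None
    if tz is not None:
        pfs = build_pf_measurements(
            store.blood_gas_for(patient_id), store.vitals_fio2_for(patient_id), cfg
        )
        qpf = qualifying_pf(pfs, tz, cfg)
        gates["qualifying_pf"] = qpf is not None
        from ardscreen.screen import positive_cxr_near

        gates["positive_cxr"] = positive_cxr_near(store.radiology_for(patient_id), tz, cfg)
        gates["non_cardiogenic"] = not cardiogenic_excluded(
            store.cardiac_events_for(patient_id), store.ecg_for(patient_id),
            index_stay, tz, cfg,
        )[0]
        gates["risk_factor"] = bool(
            find_risk_factors(store.risk_factors_for(patient_id), index_stay.admit_ts, cfg)
        )
    else:
        gates["qualifying_pf"] = gates["positive_cxr"] = False
        gates["non_cardiogenic"] = gates["risk_factor"] = False

    gates["no_fibrosis"] = not fibrosis_excluded(store.comorbidities_for(patient_id))
    gates["vent_duration"] = invasive_vent_duration(vents, cfg) >= cfg.min_vent_duration

    ards = all(gates.values())
    severity = grade_severity(qpf.ratio) if ards else None
    return ards, severity
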