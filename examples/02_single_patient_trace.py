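"""Screen one hand-built patient and inspect the gate-by-gate trace.

The patient is ventilated in the ICU with PEEP 8 (time zero), has a worst
PaO2/FiO2 of 120 (moderate stratum), a bilateral-infiltrate chest film
2 h after time zero, 48 h of invasive ventilation and pneumonia as the
risk factor — so every gate passes.  Adding an IPF comorbidity row then
flips the verdict through the fibrosis exclusion.
"""

import pandas as pd

from ardscreen.ehr_model import TABLE_COLUMNS, EhrStore
from ardscreen import screen_patient

t0 = pd.Timestamp("2016-06-01T10:00:00+00:00")
rows = {
    "patients": [{"patient_id": "P1", "birth_date": "1970-05-01",
                  "research_authorization": "true"}],
    "icu_stays": [{"patient_id": "P1", "admit_ts": "2016-06-01T06:00:00+00:00",
                   "discharge_ts": "2016-06-08T06:00:00+00:00", "unit_class": "icu"}],
    "vent_settings": [
        {"patient_id": "P1", "ts": (t0 + pd.Timedelta(hours=h)).isoformat(),
         "peep": "8", "mode": "AC/VC", "invasive": "true", "location_class": "icu"}
        for h in range(49)
    ],
    "blood_gas": [{"patient_id": "P1", "ts": "2016-06-01T12:00:00+00:00",
                   "pao2": "96.0", "fio2_lab": "0.80"}],
    "radiology": [{"patient_id": "P1", "ts": "2016-06-01T12:00:00+00:00",
                   "modality": "chest_xray",
                   "report_text": "Bilateral infiltrates are present. No pneumothorax."}],
    "risk_factors": [{"patient_id": "P1", "ts": "2016-06-01T18:00:00+00:00",
                      "category": "pneumonia", "source": "diagnosis"}],
}


def build(rows):
    frames = {t: pd.DataFrame(rows.get(t, []), columns=c).replace("", pd.NA)
              for t, c in TABLE_COLUMNS.items()}
    return EhrStore.from_frames(frames)


r = screen_patient(build(rows), "P1")
print(f"verdict: ards={r.ards}, severity={r.severity.value}, "
      f"worst P/F={r.qualifying_pf.ratio:.0f} ({r.qualifying_pf.fio2_source} FiO2)")
print("trace:")
for gate in r.trace:
    print(f"  {gate.name:16s} {'pass' if gate.passed else 'FAIL':4s}  {gate.detail}")

rows["comorbidities"] = [{"patient_id": "P1", "category": "ipf",
                          "recorded_ts": "2015-01-01T00:00:00+00:00"}]
r2 = screen_patient(build(rows), "P1")
print(f"\nwith an IPF comorbidity row: ards={r2.ards}, "
      f"exclusion={[e.value for e in r2.exclusion_reasons]}")
print("Fibrosing lung disease explains bilateral opacities without ARDS,")
print("so the screen excludes such patients outright.")
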