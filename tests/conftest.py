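import pandas as pd
import pytest

from ardscreen.ehr_model import TABLE_COLUMNS, EhrStore
from ardscreen.screen import ScreenConfig


def T(s: str) -> pd.Timestamp:
    """UTC timestamp shorthand for fixtures."""
    return pd.Timestamp(s, tz="UTC")


def build_frames(**rows_by_table) -> dict[str, pd.DataFrame]:
    """Ten raw CSV-dialect frames; unspecified tables are empty."""
    frames = {}
    for table, cols in TABLE_COLUMNS.items():
        rows = rows_by_table.get(table, [])
        frames[table] = pd.DataFrame(rows, columns=cols).replace("", pd.NA)
    return frames


def build_store(**rows_by_table) -> EhrStore:
    return EhrStore.from_frames(build_frames(**rows_by_table))


# a single hand-built patient that satisfies every screening gate:
# PEEP 8 in the ICU (time zero 2016-06-01 10:00), worst P/F 120 two hours
# later, bilateral-infiltrate chest film at +2 h, 48 h of invasive
# ventilation, pneumonia charted 12 h after admission, no cardiac history
def full_positive_rows(pid: str = "P1") -> dict[str, list[dict]]:
    t0 = pd.Timestamp("2016-06-01T10:00:00+00:00")
    vent_rows = [
        {"patient_id": pid, "ts": (t0 + pd.Timedelta(hours=h)).isoformat(),
         "peep": "8", "mode": "AC/VC", "invasive": "true", "location_class": "icu"}
        for h in range(0, 49)
    ]
    return dict(
        patients=[{"patient_id": pid, "birth_date": "1970-05-01",
                   "research_authorization": "true"}],
        icu_stays=[{"patient_id": pid, "admit_ts": "2016-06-01T06:00:00+00:00",
                    "discharge_ts": "2016-06-08T06:00:00+00:00", "unit_class": "icu"}],
        vent_settings=vent_rows,
        blood_gas=[{"patient_id": pid, "ts": "2016-06-01T12:00:00+00:00",
                    "pao2": "96.0", "fio2_lab": "0.80"}],
        radiology=[{"patient_id": pid, "ts": "2016-06-01T12:00:00+00:00",
                    "modality": "chest_xray",
                    "report_text": "Bilateral infiltrates are present. No pneumothorax."}],
        risk_factors=[{"patient_id": pid, "ts": "2016-06-01T18:00:00+00:00",
                       "category": "pneumonia", "source": "diagnosis"}],
    )


@pytest.fixture
def cfg() -> ScreenConfig:
    return ScreenConfig()


@pytest.fixture
def positive_store() -> EhrStore:
    return build_store(**full_positive_rows())
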