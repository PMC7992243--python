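"""Typed data model for ICU EHR extracts.

Ten flat CSV tables (one per clinical domain) are loaded into an
:class:`EhrStore`: demographics/authorization, ICU stays, ventilator
settings, arterial blood gases, vital-sign FiO2, chest imaging reports,
comorbidities, ARDS risk-factor events, cardiac events and ECG reports.
Loading validates every row against physiological and structural
invariants, normalizes units (FiO2 percent -> fraction, timestamps -> UTC)
and drops — never silently edits — rows that fail, logging a count per
table.  Rows referencing an unknown patient are dropped as orphans so the
store is always referentially closed.

FiO2 dialect: fractions in [0.21, 1.0] are kept as-is; values in
[21, 100] are read as percentages and divided by 100; anything in
(1.0, 21) is ambiguous between the two conventions and is rejected, as is
anything below 0.21 (sub-atmospheric) or above 100.

Timestamps are ISO-8601; timezone-naive values are assumed UTC (a warning
is logged with the count), so all window arithmetic downstream happens in
one clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

FIO2_FLOOR = 0.21  # room air; nothing inspirable is below this


class UnitClass(str, Enum):
    icu = "icu"
    procedural_area = "procedural_area"


class Modality(str, Enum):
    chest_xray = "chest_xray"
    other = "other"


class ComorbidityCategory(str, Enum):
    # Charlson comorbidity index categories
    myocardial_infarction = "myocardial_infarction"
    congestive_heart_failure = "congestive_heart_failure"
    peripheral_vascular_disease = "peripheral_vascular_disease"
    cerebrovascular_disease = "cerebrovascular_disease"
    dementia = "dementia"
    chronic_pulmonary_disease = "chronic_pulmonary_disease"
    rheumatic_disease = "rheumatic_disease"
    peptic_ulcer_disease = "peptic_ulcer_disease"
    mild_liver_disease = "mild_liver_disease"
    diabetes = "diabetes"
    diabetes_with_complications = "diabetes_with_complications"
    hemiplegia = "hemiplegia"
    renal_disease = "renal_disease"
    malignancy = "malignancy"
    severe_liver_disease = "severe_liver_disease"
    metastatic_tumor = "metastatic_tumor"
    aids = "aids"
    # fibrosing lung disease — triggers the screen's exclusion gate
    ipf = "ipf"
    ild = "ild"
    pulmonary_fibrosis = "pulmonary_fibrosis"


FIBROSIS_CATEGORIES = frozenset(
    {
        ComorbidityCategory.ipf,
        ComorbidityCategory.ild,
        ComorbidityCategory.pulmonary_fibrosis,
    }
)


class RiskFactorCategory(str, Enum):
    sepsis_septic_shock = "sepsis_septic_shock"
    pneumonia = "pneumonia"
    aspiration = "aspiration"
    pancreatitis = "pancreatitis"
    trauma = "trauma"
    drug_overdose = "drug_overdose"
    shock = "shock"
    multiple_transfusion = "multiple_transfusion"


class RiskFactorSource(str, Enum):
    diagnosis = "diagnosis"
    note = "note"


class CardiacCategory(str, Enum):
    cardiogenic_pulmonary_edema = "cardiogenic_pulmonary_edema"
    cardiogenic_shock = "cardiogenic_shock"
    adhf_positive = "adhf_positive"
    cad_history = "cad_history"
    chf_history = "chf_history"


ACUTE_CARDIAC = frozenset(
    {
        CardiacCategory.cardiogenic_pulmonary_edema,
        CardiacCategory.cardiogenic_shock,
        CardiacCategory.adhf_positive,
    }
)
CARDIAC_HISTORY = frozenset({CardiacCategory.cad_history, CardiacCategory.chf_history})


# ---------------------------------------------------------------------------
# Row records (lightweight views over the store's tables)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_date: Optional[date]
    research_authorization: bool


@dataclass(frozen=True)
class IcuStay:
    patient_id: str
    admit_ts: pd.Timestamp
    discharge_ts: pd.Timestamp
    unit_class: UnitClass


@dataclass(frozen=True)
class VentRecord:
    patient_id: str
    ts: pd.Timestamp
    peep: float
    mode: str
    invasive: bool
    location_class: UnitClass


@dataclass(frozen=True)
class BloodGasResult:
    patient_id: str
    ts: pd.Timestamp
    pao2: float
    fio2_lab: Optional[float]


@dataclass(frozen=True)
class VitalFio2:
    patient_id: str
    ts: pd.Timestamp
    fio2: float


@dataclass(frozen=True)
class ImagingReport:
    patient_id: str
    ts: pd.Timestamp
    modality: Modality
    report_text: str


@dataclass(frozen=True)
class ComorbidityEntry:
    patient_id: str
    category: ComorbidityCategory
    recorded_ts: pd.Timestamp


@dataclass(frozen=True)
class RiskFactorEvent:
    patient_id: str
    ts: pd.Timestamp
    category: RiskFactorCategory
    source: RiskFactorSource


@dataclass(frozen=True)
class CardiacEvent:
    patient_id: str
    ts: pd.Timestamp
    category: CardiacCategory


@dataclass(frozen=True)
class EcgReport:
    patient_id: str
    ts: pd.Timestamp
    findings_text: str


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

TABLE_FILES = {
    "patients": "patients.csv",
    "icu_stays": "icu_stays.csv",
    "vent_settings": "vent_settings.csv",
    "blood_gas": "blood_gas.csv",
    "vitals_fio2": "vitals_fio2.csv",
    "radiology": "radiology.csv",
    "comorbidities": "comorbidities.csv",
    "risk_factors": "risk_factors.csv",
    "cardiac_events": "cardiac_events.csv",
    "ecg": "ecg.csv",
}

TABLE_COLUMNS = {
    "patients": ["patient_id", "birth_date", "research_authorization"],
    "icu_stays": ["patient_id", "admit_ts", "discharge_ts", "unit_class"],
    "vent_settings": ["patient_id", "ts", "peep", "mode", "invasive", "location_class"],
    "blood_gas": ["patient_id", "ts", "pao2", "fio2_lab"],
    "vitals_fio2": ["patient_id", "ts", "fio2"],
    "radiology": ["patient_id", "ts", "modality", "report_text"],
    "comorbidities": ["patient_id", "category", "recorded_ts"],
    "risk_factors": ["patient_id", "ts", "category", "source"],
    "cardiac_events": ["patient_id", "ts", "category"],
    "ecg": ["patient_id", "ts", "findings_text"],
}

_TS_COLUMNS = {
    "icu_stays": ["admit_ts", "discharge_ts"],
    "vent_settings": ["ts"],
    "blood_gas": ["ts"],
    "vitals_fio2": ["ts"],
    "radiology": ["ts"],
    "comorbidities": ["recorded_ts"],
    "risk_factors": ["ts"],
    "cardiac_events": ["ts"],
    "ecg": ["ts"],
}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def normalize_fio2(values: pd.Series) -> pd.Series:
    """Normalize an FiO2 column to fractions; invalid values become NaN.

    Fractions in [0.21, 1.0] pass through; [21, 100] is read as percent.
    """
    v = pd.to_numeric(values, errors="coerce")
    out = pd.Series(np.nan, index=v.index, dtype=float)
    frac = (v >= FIO2_FLOOR) & (v <= 1.0)
    pct = (v >= 100 * FIO2_FLOOR) & (v <= 100.0)
    out[frac] = v[frac]
    out[pct] = v[pct] / 100.0
    return out


def _parse_bool(values: pd.Series) -> pd.Series:
    s = values.astype("string").str.strip().str.lower()
    return s.map(_BOOL_MAP)


def _parse_ts(values: pd.Series, table: str, col: str) -> pd.Series:
    s = values.astype("string").str.strip()
    parsed = pd.to_datetime(s, errors="coerce", utc=True, format="ISO8601")
    has_tz = s.str.contains(r"(?:Z|[+-]\d{2}:?\d{2})$", na=False)
    n_naive = int((parsed.notna() & ~has_tz).sum())
    if n_naive:
        logger.warning(
            "%s.%s: %d timezone-naive timestamps assumed UTC", table, col, n_naive
        )
    return parsed


# ---------------------------------------------------------------------------
# The store
# ---------------------------------------------------------------------------


@dataclass
class EhrStore:
    """Validated, referentially closed set of per-cohort EHR tables.

    Tables are pandas DataFrames with normalized dtypes; the ``*_for``
    accessors return typed per-patient row records sorted by time.
    """

    tables: dict[str, pd.DataFrame]
    meta: dict = field(default_factory=dict)
    rejection_counts: dict[str, int] = field(default_factory=dict)
    _groups: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frames(cls, frames: dict[str, pd.DataFrame], meta: dict | None = None) -> "EhrStore":
        """Validate and normalize raw tables (strings allowed) into a store."""
        missing = set(TABLE_FILES) - set(frames)
        if missing:
            raise SchemaError(f"missing tables: {', '.join(sorted(missing))}")
        rejections: dict[str, int] = {}
        clean: dict[str, pd.DataFrame] = {}
        for name in TABLE_FILES:
            df = frames[name].copy()
            for col in TABLE_COLUMNS[name]:
                if col not in df.columns:
                    raise SchemaError(f"table '{name}' is missing required column '{col}'")
            df = df[TABLE_COLUMNS[name]]  # drop unknown columns, fix order
            df, n_rej = _VALIDATORS[name](df)
            rejections[name] = n_rej
            clean[name] = df.reset_index(drop=True)

        # referential integrity: drop orphans
        known = set(clean["patients"]["patient_id"])
        for name in TABLE_FILES:
            if name == "patients":
                continue
            df = clean[name]
            orphan = ~df["patient_id"].isin(known)
            n_orphan = int(orphan.sum())
            if n_orphan:
                logger.warning("%s: dropped %d orphan rows (unknown patient_id)", name, n_orphan)
                rejections[name] += n_orphan
                clean[name] = df[~orphan].reset_index(drop=True)

        for name, n in rejections.items():
            if n:
                logger.info("%s: rejected %d invalid rows", name, n)
        return cls(tables=clean, meta=dict(meta or {}), rejection_counts=rejections)

    # -- accessors ----------------------------------------------------------

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.tables["patients"]["patient_id"])

    def _rows(self, table: str, patient_id: str, sort_col: str | None) -> pd.DataFrame:
        # per-patient group index, built lazily once per table
        if table not in self._groups:
            self._groups[table] = {
                pid: grp for pid, grp in self.tables[table].groupby("patient_id", sort=False)
            }
        df = self._groups[table].get(patient_id)
        if df is None:
            return self.tables[table].iloc[0:0]
        if sort_col is not None:
            df = df.sort_values(sort_col, kind="mergesort")
        return df

    def patient(self, patient_id: str) -> PatientRecord:
        df = self._rows("patients", patient_id, None)
        if df.empty:
            raise KeyError(f"unknown patient_id: {patient_id}")
        r = df.iloc[0]
        bd = r["birth_date"]
        return PatientRecord(
            patient_id=r["patient_id"],
            birth_date=None if pd.isna(bd) else bd.date(),
            research_authorization=bool(r["research_authorization"]),
        )

    def icu_stays_for(self, patient_id: str) -> list[IcuStay]:
        return [
            IcuStay(r.patient_id, r.admit_ts, r.discharge_ts, UnitClass(r.unit_class))
            for r in self._rows("icu_stays", patient_id, "admit_ts").itertuples()
        ]

    def vents_for(self, patient_id: str) -> list[VentRecord]:
        return [
            VentRecord(r.patient_id, r.ts, float(r.peep), r.mode or "", bool(r.invasive),
                       UnitClass(r.location_class))
            for r in self._rows("vent_settings", patient_id, "ts").itertuples()
        ]

    def blood_gas_for(self, patient_id: str) -> list[BloodGasResult]:
        return [
            BloodGasResult(r.patient_id, r.ts, float(r.pao2),
                           None if pd.isna(r.fio2_lab) else float(r.fio2_lab))
            for r in self._rows("blood_gas", patient_id, "ts").itertuples()
        ]

    def vitals_fio2_for(self, patient_id: str) -> list[VitalFio2]:
        return [
            VitalFio2(r.patient_id, r.ts, float(r.fio2))
            for r in self._rows("vitals_fio2", patient_id, "ts").itertuples()
        ]

    def radiology_for(self, patient_id: str) -> list[ImagingReport]:
        return [
            ImagingReport(r.patient_id, r.ts, Modality(r.modality), r.report_text or "")
            for r in self._rows("radiology", patient_id, "ts").itertuples()
        ]

    def comorbidities_for(self, patient_id: str) -> list[ComorbidityEntry]:
        return [
            ComorbidityEntry(r.patient_id, ComorbidityCategory(r.category), r.recorded_ts)
            for r in self._rows("comorbidities", patient_id, "recorded_ts").itertuples()
        ]

    def risk_factors_for(self, patient_id: str) -> list[RiskFactorEvent]:
        return [
            RiskFactorEvent(r.patient_id, r.ts, RiskFactorCategory(r.category),
                            RiskFactorSource(r.source))
            for r in self._rows("risk_factors", patient_id, "ts").itertuples()
        ]

    def cardiac_events_for(self, patient_id: str) -> list[CardiacEvent]:
        return [
            CardiacEvent(r.patient_id, r.ts, CardiacCategory(r.category))
            for r in self._rows("cardiac_events", patient_id, "ts").itertuples()
        ]

    def ecg_for(self, patient_id: str) -> list[EcgReport]:
        return [
            EcgReport(r.patient_id, r.ts, r.findings_text or "")
            for r in self._rows("ecg", patient_id, "ts").itertuples()
        ]

    def row_counts(self) -> dict[str, int]:
        return {name: int(len(df)) for name, df in self.tables.items()}


# ---------------------------------------------------------------------------
# Per-table validators: return (clean frame, rejected-row count)
# ---------------------------------------------------------------------------


def _validate_patients(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    pid = df["patient_id"].astype("string").str.strip()
    bd = pd.to_datetime(df["birth_date"].astype("string").str.strip(), errors="coerce")
    auth = _parse_bool(df["research_authorization"])
    ok = pid.notna() & (pid != "") & auth.notna()
    # birth_date may be missing (eligibility gate handles it); a present but
    # unparseable one rejects the row
    raw_bd = df["birth_date"].astype("string").str.strip().fillna("")
    ok &= (raw_bd == "") | bd.notna()
    out = pd.DataFrame({"patient_id": pid, "birth_date": bd, "research_authorization": auth})[ok]
    out = out.drop_duplicates(subset="patient_id", keep="first")
    return out, n0 - len(out)


def _validate_icu_stays(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    admit = _parse_ts(df["admit_ts"], "icu_stays", "admit_ts")
    disch = _parse_ts(df["discharge_ts"], "icu_stays", "discharge_ts")
    unit = df["unit_class"].astype("string").str.strip()
    ok = admit.notna() & disch.notna() & (admit < disch)
    ok &= unit.isin([u.value for u in UnitClass])
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype("string").str.strip(),
            "admit_ts": admit,
            "discharge_ts": disch,
            "unit_class": unit,
        }
    )[ok]
    # intra-patient overlap: keep the earlier stay, reject overlapping later rows
    keep_idx = []
    for _, grp in out.sort_values("admit_ts", kind="mergesort").groupby("patient_id"):
        horizon = None
        for idx, row in grp.iterrows():
            if horizon is not None and row["admit_ts"] < horizon:
                continue
            keep_idx.append(idx)
            horizon = row["discharge_ts"]
    out = out.loc[sorted(keep_idx)]
    return out, n0 - len(out)


def _validate_vents(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    ts = _parse_ts(df["ts"], "vent_settings", "ts")
    peep = pd.to_numeric(df["peep"], errors="coerce")
    inv = _parse_bool(df["invasive"])
    loc = df["location_class"].astype("string").str.strip()
    ok = ts.notna() & peep.notna() & np.isfinite(peep.fillna(np.nan)) & (peep >= 0)
    ok &= inv.notna() & loc.isin([u.value for u in UnitClass])
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype("string").str.strip(),
            "ts": ts,
            "peep": peep,
            "mode": df["mode"].astype("string").str.strip().fillna(""),
            "invasive": inv,
            "location_class": loc,
        }
    )[ok]
    return out, n0 - len(out)


def _validate_blood_gas(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    ts = _parse_ts(df["ts"], "blood_gas", "ts")
    pao2 = pd.to_numeric(df["pao2"], errors="coerce")
    raw_fio2 = df["fio2_lab"].astype("string").str.strip().fillna("")
    fio2 = normalize_fio2(df["fio2_lab"])
    ok = ts.notna() & pao2.notna() & np.isfinite(pao2.fillna(np.nan)) & (pao2 > 0)
    # a present but invalid lab FiO2 rejects the row; absent is fine
    ok &= (raw_fio2 == "") | fio2.notna()
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype("string").str.strip(),
            "ts": ts,
            "pao2": pao2,
            "fio2_lab": fio2,
        }
    )[ok]
    return out, n0 - len(out)


def _validate_vitals_fio2(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    ts = _parse_ts(df["ts"], "vitals_fio2", "ts")
    fio2 = normalize_fio2(df["fio2"])
    ok = ts.notna() & fio2.notna()
    out = pd.DataFrame(
        {"patient_id": df["patient_id"].astype("string").str.strip(), "ts": ts, "fio2": fio2}
    )[ok]
    return out, n0 - len(out)


def _validate_radiology(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    ts = _parse_ts(df["ts"], "radiology", "ts")
    modality = df["modality"].astype("string").str.strip()
    text = df["report_text"].astype("string").fillna("")
    ok = ts.notna() & modality.isin([m.value for m in Modality])
    ok &= (modality != Modality.chest_xray.value) | (text.str.strip() != "")
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype("string").str.strip(),
            "ts": ts,
            "modality": modality,
            "report_text": text,
        }
    )[ok]
    return out, n0 - len(out)


def _validate_comorbidities(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    ts = _parse_ts(df["recorded_ts"], "comorbidities", "recorded_ts")
    cat = df["category"].astype("string").str.strip()
    ok = ts.notna() & cat.isin([c.value for c in ComorbidityCategory])
    out = pd.DataFrame(
        {"patient_id": df["patient_id"].astype("string").str.strip(), "category": cat,
         "recorded_ts": ts}
    )[ok]
    return out, n0 - len(out)


def _validate_risk_factors(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    ts = _parse_ts(df["ts"], "risk_factors", "ts")
    cat = df["category"].astype("string").str.strip()
    src = df["source"].astype("string").str.strip()
    ok = ts.notna() & cat.isin([c.value for c in RiskFactorCategory])
    ok &= src.isin([s.value for s in RiskFactorSource])
    out = pd.DataFrame(
        {"patient_id": df["patient_id"].astype("string").str.strip(), "ts": ts,
         "category": cat, "source": src}
    )[ok]
    return out, n0 - len(out)


def _validate_cardiac(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    ts = _parse_ts(df["ts"], "cardiac_events", "ts")
    cat = df["category"].astype("string").str.strip()
    ok = ts.notna() & cat.isin([c.value for c in CardiacCategory])
    out = pd.DataFrame(
        {"patient_id": df["patient_id"].astype("string").str.strip(), "ts": ts, "category": cat}
    )[ok]
    return out, n0 - len(out)


def _validate_ecg(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n0 = len(df)
    ts = _parse_ts(df["ts"], "ecg", "ts")
    text = df["findings_text"].astype("string").fillna("")
    ok = ts.notna() & (text.str.strip() != "")
    out = pd.DataFrame(
        {"patient_id": df["patient_id"].astype("string").str.strip(), "ts": ts,
         "findings_text": text}
    )[ok]
    return out, n0 - len(out)


_VALIDATORS = {
    "patients": _validate_patients,
    "icu_stays": _validate_icu_stays,
    "vent_settings": _validate_vents,
    "blood_gas": _validate_blood_gas,
    "vitals_fio2": _validate_vitals_fio2,
    "radiology": _validate_radiology,
    "comorbidities": _validate_comorbidities,
    "risk_factors": _validate_risk_factors,
    "cardiac_events": _validate_cardiac,
    "ecg": _validate_ecg,
}


# ---------------------------------------------------------------------------
# Directory I/O
# ---------------------------------------------------------------------------


def load_store(data_dir: str | Path, config=None) -> EhrStore:
    """Load and validate the ten-table CSV extract in ``data_dir``.

    Raises :class:`SchemaError` naming the first missing file; individual
    invalid rows are dropped and counted, never fatal.
    """
    data_dir = Path(data_dir)
    frames = {}
    for name, fname in TABLE_FILES.items():
        path = data_dir / fname
        if not path.exists():
            raise SchemaError(f"required file not found: {fname} (in {data_dir})")
        frames[name] = pd.read_csv(path, dtype="string", keep_default_na=False)
        # empty string = missing
        frames[name] = frames[name].replace("", pd.NA)
    meta = {"data_dir": str(data_dir)}
    if config is not None:
        meta["config"] = config.model_dump() if hasattr(config, "model_dump") else dict(config)
    return EhrStore.from_frames(frames, meta=meta)


def _ts_to_str(s: pd.Series) -> pd.Series:
    return s.dt.strftime("%Y-%m-%dT%H:%M:%S%z").str.replace(r"\+0000$", "+00:00", regex=True)


def write_store(store: EhrStore, out_dir: str | Path) -> None:
    """Write the store back to the ten-file CSV layout (UTC ISO timestamps)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, fname in TABLE_FILES.items():
        df = store.tables[name].copy()
        for col in _TS_COLUMNS.get(name, []):
            df[col] = _ts_to_str(df[col])
        if name == "patients":
            df["birth_date"] = df["birth_date"].dt.strftime("%Y-%m-%d")
        for col in ("research_authorization", "invasive"):
            if col in df.columns:
                df[col] = df[col].map({True: "true", False: "false"})
        df.to_csv(out_dir / fname, index=False)


# ---------------------------------------------------------------------------
# Screen-result serialization
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "patient_id",
    "ards",
    "severity",
    "time_zero",
    "vent_mode",
    "pf_ratio",
    "pf_pao2",
    "pf_fio2",
    "pf_fio2_source",
    "exclusion_reasons",
]


def write_results(results, out: str | Path) -> None:
    """Write per-patient screen verdicts to CSV (one row per patient).

    Columns: verdict, severity, time zero, qualifying P/F with provenance,
    semicolon-joined exclusion reasons, and one pass/fail flag column per
    screening gate (empty = not evaluated due to short-circuit).
    """
    if not results:
        raise ValueError("results must be non-empty")
    from .screen import GATE_ORDER  # local import to avoid a cycle

    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id,
            "ards": "true" if r.ards else "false",
            "severity": r.severity.value,
            "time_zero": "" if r.time_zero is None else r.time_zero.isoformat(),
            "vent_mode": r.vent_mode or "",
            "pf_ratio": "" if r.qualifying_pf is None else f"{r.qualifying_pf.ratio:.6g}",
            "pf_pao2": "" if r.qualifying_pf is None else f"{r.qualifying_pf.pao2:.6g}",
            "pf_fio2": "" if r.qualifying_pf is None else f"{r.qualifying_pf.fio2:.6g}",
            "pf_fio2_source": "" if r.qualifying_pf is None else r.qualifying_pf.fio2_source,
            "exclusion_reasons": ";".join(e.value for e in r.exclusion_reasons),
        }
        evaluated = {g.name: g for g in r.trace}
        for gate in GATE_ORDER:
            g = evaluated.get(gate)
            row[f"gate_{gate}"] = "" if g is None else ("pass" if g.passed else "fail")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype="string", keep_default_na=False)
    for col in ("patient_id", "ards"):
        if col not in df.columns:
            raise SchemaError(f"results file {path} missing column '{col}'")
    return df
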