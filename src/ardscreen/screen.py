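"""Six-step rule-based screen for ARDS per the Berlin definition.

The screen walks each patient through sequential gates, mirroring how a
retrospective chart-review algorithm is applied to an ICU EHR extract:

1. eligibility — research authorization given and age >= 18 at ICU admit;
2. time zero — the first PEEP >= 5 cm H2O charted in an ICU area during an
   ICU stay, with the nearest ventilator mode;
3. hypoxemia — a PaO2/FiO2 ratio <= 300 at or after time zero, built from
   lab-matched FiO2 or, failing that, the nearest vital-sign FiO2 within
   +/- 15 min of the PaO2 draw;
4. imaging — a chest X-ray within +/- 12 h of time zero whose report pairs
   "bilateral" with infiltrates/opacities/edema;
5. fibrosing lung disease exclusion (IPF / ILD / pulmonary fibrosis);
6. invasive ventilation >= 12 h (episodes merged across gaps <= 1 h);
7. at least one ARDS risk factor within +/- 72 h of ICU admission;
8. cardiogenic exclusion — acute cardiogenic edema / cardiogenic shock /
   positive ADHF during the index stay, any CAD/CHF history, or an ECG with
   new ST changes or LBBB within +/- 24 h of time zero.

Evaluation short-circuits at the first failing gate (that gate is the
recorded exclusion reason) but the trace keeps every gate evaluated, so a
negative verdict is always reproducible gate by gate.  Severity grades the
worst (minimum) qualifying ratio: mild 200-300, moderate 100-199,
severe < 100.

All thresholds and windows live in :class:`ScreenConfig` and are
deliberately tunable; the defaults are the published operating point.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator

from .ehr_model import (
    ACUTE_CARDIAC,
    CARDIAC_HISTORY,
    FIBROSIS_CATEGORIES,
    BloodGasResult,
    CardiacEvent,
    ComorbidityEntry,
    EcgReport,
    EhrStore,
    IcuStay,
    ImagingReport,
    Modality,
    PatientRecord,
    RiskFactorCategory,
    RiskFactorEvent,
    UnitClass,
    VentRecord,
    VitalFio2,
)
from .errors import ContractError

logger = logging.getLogger(__name__)


class ScreenConfig(BaseModel):
    """Thresholds and time windows of the screening algorithm.

    Units: pressures in cm H2O, ``fio2_match_window`` in minutes, all other
    windows/durations in hours, ``keyword_proximity`` in tokens.
    """

    peep_threshold: float = Field(5.0, gt=0)
    pf_threshold: float = Field(300.0, gt=0)
    fio2_match_window: float = Field(15.0, gt=0)
    cxr_window: float = Field(12.0, gt=0)
    ecg_window: float = Field(24.0, gt=0)
    risk_factor_window: float = Field(72.0, gt=0)
    min_vent_duration: float = Field(12.0, gt=0)
    vent_gap_merge: float = Field(1.0, gt=0)
    keyword_proximity: int = Field(3, gt=0)

    @field_validator("pf_threshold")
    @classmethod
    def _warn_outside_berlin(cls, v: float) -> float:
        if v > 300.0:
            logger.warning(
                "pf_threshold %.1f exceeds 300; this leaves the Berlin definition", v
            )
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class Severity(str, Enum):
    none = "none"
    mild = "mild"
    moderate = "moderate"
    severe = "severe"


class ExclusionReason(str, Enum):
    no_authorization = "no_authorization"
    under_18 = "under_18"
    no_time_zero = "no_time_zero"
    no_qualifying_pf = "no_qualifying_pf"
    no_positive_cxr = "no_positive_cxr"
    fibrosis = "fibrosis"
    vent_under_min = "vent_under_min"
    no_risk_factor = "no_risk_factor"
    cardiogenic = "cardiogenic"


# gate name -> exclusion reason recorded when the gate fails
GATE_ORDER = [
    "eligibility",
    "time_zero",
    "qualifying_pf",
    "positive_cxr",
    "no_fibrosis",
    "vent_duration",
    "risk_factor",
    "non_cardiogenic",
]


@dataclass(frozen=True)
class PFMeasurement:
    """A matched PaO2/FiO2 pair; ``ts`` is the PaO2 draw time."""

    ts: object
    pao2: float
    fio2: float
    fio2_source: str  # "lab" | "vitals"
    ratio: float


@dataclass(frozen=True)
class GateRecord:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ScreenResult:
    patient_id: str
    ards: bool
    severity: Severity
    time_zero: Optional[object] = None
    vent_mode: Optional[str] = None
    qualifying_pf: Optional[PFMeasurement] = None
    exclusion_reasons: list[ExclusionReason] = field(default_factory=list)
    trace: list[GateRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Individual gates
# ---------------------------------------------------------------------------


def check_eligibility(patient: PatientRecord, index_stay: Optional[IcuStay]):
    """Eligible iff research authorization and age >= 18 at ICU admission.

    Age is the floor of whole years between birth date and admit; a missing
    birth date is treated as ineligible (cannot establish adulthood).
    Returns (eligible, reason-or-None).
    """
    if not patient.research_authorization:
        return False, ExclusionReason.no_authorization
    if index_stay is None:
        # no ICU stay to index age against; the time-zero gate will fail
        return True, None
    if patient.birth_date is None:
        logger.info("%s: missing birth_date, treated as under 18", patient.patient_id)
        return False, ExclusionReason.under_18
    admit = index_stay.admit_ts
    age = admit.year - patient.birth_date.year - (
        (admit.month, admit.day) < (patient.birth_date.month, patient.birth_date.day)
    )
    if age < 18:
        return False, ExclusionReason.under_18
    return True, None


def find_time_zero(
    vents: Sequence[VentRecord],
    stays: Sequence[IcuStay],
    cfg: ScreenConfig,
):
    """First PEEP >= threshold charted in an ICU area during an ICU stay.

    Returns (time_zero, nearest_mode, containing_stay); all None when no
    record qualifies. If the qualifying record has an empty mode the mode
    comes from the nearest-in-time ICU ventilator record with one.
    """
    icu_stays = [s for s in stays if s.unit_class == UnitClass.icu]
    ordered = sorted(vents, key=lambda v: v.ts)
    for v in ordered:
        if v.location_class != UnitClass.icu or v.peep < cfg.peep_threshold:
            continue
        stay = next(
            (s for s in icu_stays if s.admit_ts <= v.ts <= s.discharge_ts), None
        )
        if stay is None:
            continue
        mode = v.mode
        if not mode:
            with_mode = [
                w for w in ordered if w.mode and w.location_class == UnitClass.icu
            ]
            if with_mode:
                mode = min(with_mode, key=lambda w: (abs(w.ts - v.ts), w.ts)).mode
        return v.ts, mode or None, stay
    return None, None, None


def build_pf_measurements(
    gases: Sequence[BloodGasResult],
    vitals: Sequence[VitalFio2],
    cfg: ScreenConfig,
) -> list[PFMeasurement]:
    """Pair each PaO2 with an FiO2 and compute the ratio.

    Lab FiO2 on the same blood-gas result wins; otherwise the vital-sign
    FiO2 nearest in time within the match window is used (ties broken
    toward the earlier record). A PaO2 with neither yields no measurement.
    """
    out: list[PFMeasurement] = []
    window = cfg.fio2_match_window * 60.0  # seconds
    vitals_sorted = sorted(vitals, key=lambda v: v.ts)
    for gas in sorted(gases, key=lambda g: g.ts):
        if gas.fio2_lab is not None:
            fio2, source = gas.fio2_lab, "lab"
        else:
            in_window = [
                v for v in vitals_sorted
                if abs((v.ts - gas.ts).total_seconds()) <= window
            ]
            if not in_window:
                continue
            best = min(
                in_window,
                key=lambda v: (abs((v.ts - gas.ts).total_seconds()), v.ts),
            )
            fio2, source = best.fio2, "vitals"
        out.append(
            PFMeasurement(
                ts=gas.ts, pao2=gas.pao2, fio2=fio2, fio2_source=source,
                ratio=gas.pao2 / fio2,
            )
        )
    return out


def qualifying_pf(
    pfs: Sequence[PFMeasurement], time_zero, cfg: ScreenConfig
) -> Optional[PFMeasurement]:
    """Worst (minimum) ratio <= threshold at or after time zero; ties -> earliest."""
    candidates = [p for p in pfs if p.ts >= time_zero and p.ratio <= cfg.pf_threshold]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (p.ratio, p.ts))


_KEYWORD_STEMS = ("infiltrat", "opacit", "opacif", "edema")
_BILATERAL_STEM = "bilateral"
_TOKEN_RE = re.compile(r"[0-9a-z]+")


def radiology_positive(report: ImagingReport, cfg: Optional[ScreenConfig] = None) -> bool:
    """True iff 'bilateral' precedes an infiltrate/opacity/edema token.

    The report is lowercased and split into period-delimited sentences;
    within a sentence, a token stemming to 'bilateral' must occur at most
    ``keyword_proximity`` tokens before a token stemming to one of
    infiltrate(s)/opacity(-ies)/opacification/edema.  No negation handling.
    """
    cfg = cfg or ScreenConfig()
    text = (report.report_text or "").lower()
    if not text.strip():
        return False
    for sentence in text.split("."):
        tokens = _TOKEN_RE.findall(sentence)
        bilateral_at = [i for i, t in enumerate(tokens) if t.startswith(_BILATERAL_STEM)]
        if not bilateral_at:
            continue
        keyword_at = [
            j for j, t in enumerate(tokens) if t.startswith(_KEYWORD_STEMS)
        ]
        for i in bilateral_at:
            for j in keyword_at:
                if 0 < j - i <= cfg.keyword_proximity:
                    return True
    return False


def positive_cxr_near(
    reports: Sequence[ImagingReport], time_zero, cfg: ScreenConfig
) -> bool:
    """Any positive chest X-ray report within +/- cxr_window hours of time zero."""
    window = cfg.cxr_window * 3600.0
    return any(
        r.modality == Modality.chest_xray
        and abs((r.ts - time_zero).total_seconds()) <= window
        and radiology_positive(r, cfg)
        for r in reports
    )


def fibrosis_excluded(comorbidities: Sequence[ComorbidityEntry]) -> bool:
    """True iff any IPF / ILD / pulmonary-fibrosis comorbidity is on record."""
    return any(c.category in FIBROSIS_CATEGORIES for c in comorbidities)


def invasive_vent_duration(vents: Sequence[VentRecord], cfg: ScreenConfig) -> float:
    """Total invasive-ventilation hours, summing charted episodes.

    Consecutive invasive records with gaps <= ``vent_gap_merge`` hours form
    one episode; an episode's duration is last minus first timestamp. This
    approximates a charting-based ventilation-duration algorithm; isolated
    single records contribute zero.
    """
    times = sorted(v.ts for v in vents if v.invasive)
    if len(times) < 2:
        return 0.0
    merge = cfg.vent_gap_merge * 3600.0
    total = 0.0
    ep_start = ep_end = times[0]
    for ts in times[1:]:
        if (ts - ep_end).total_seconds() <= merge:
            ep_end = ts
        else:
            total += (ep_end - ep_start).total_seconds()
            ep_start = ep_end = ts
    total += (ep_end - ep_start).total_seconds()
    return total / 3600.0


def find_risk_factors(
    events: Sequence[RiskFactorEvent], icu_admit, cfg: ScreenConfig
) -> set[RiskFactorCategory]:
    """ARDS risk-factor categories recorded within +/- the window of ICU admit."""
    window = cfg.risk_factor_window * 3600.0
    return {
        e.category
        for e in events
        if abs((e.ts - icu_admit).total_seconds()) <= window
    }


_ECG_PATTERNS = re.compile(
    r"(new\s+st[\s-]*(segment\s+)?(change|elevation|depression))"
    r"|(left\s+bundle\s+branch\s+block)"
    r"|(\blbbb\b)",
    re.IGNORECASE,
)


def cardiogenic_excluded(
    cardiac: Sequence[CardiacEvent],
    ecgs: Sequence[EcgReport],
    index_stay: IcuStay,
    time_zero,
    cfg: ScreenConfig,
):
    """Cardiogenic-edema exclusion; returns (excluded, list of reasons).

    Excludes on (a) an acute event (cardiogenic pulmonary edema, cardiogenic
    shock, positive ADHF) during the index ICU stay, (b) any CAD/CHF history
    regardless of time, or (c) an ECG within +/- ecg_window hours of time
    zero reporting new ST changes or left bundle branch block.
    """
    reasons: list[str] = []
    for ev in cardiac:
        if ev.category in ACUTE_CARDIAC:
            if index_stay.admit_ts <= ev.ts <= index_stay.discharge_ts:
                reasons.append(f"acute:{ev.category.value}")
        elif ev.category in CARDIAC_HISTORY:
            reasons.append(f"history:{ev.category.value}")
    window = cfg.ecg_window * 3600.0
    for ecg in ecgs:
        if abs((ecg.ts - time_zero).total_seconds()) <= window and _ECG_PATTERNS.search(
            ecg.findings_text
        ):
            reasons.append("ecg:new_st_or_lbbb")
    return bool(reasons), reasons


def grade_severity(ratio: float) -> Severity:
    """Berlin severity stratum for a qualifying P/F ratio in (0, 300]."""
    if not (0 < ratio <= 300):
        raise ContractError(f"P/F ratio {ratio} outside (0, 300]")
    if ratio < 100:
        return Severity.severe
    if ratio < 200:
        return Severity.moderate
    return Severity.mild


# ---------------------------------------------------------------------------
# Per-patient and per-cohort screening
# ---------------------------------------------------------------------------


def screen_patient(
    store: EhrStore, patient_id: str, cfg: Optional[ScreenConfig] = None
) -> ScreenResult:
    """Run every gate in order for one patient; short-circuit on failure.

    The first failing gate supplies the exclusion reason; the trace records
    each gate actually evaluated with its outcome.
    """
    cfg = cfg or ScreenConfig()
    patient = store.patient(patient_id)
    stays = store.icu_stays_for(patient_id)
    vents = store.vents_for(patient_id)
    result = ScreenResult(patient_id=patient_id, ards=False, severity=Severity.none)

    def fail(gate: str, reason: ExclusionReason, detail: str = "") -> ScreenResult:
        result.trace.append(GateRecord(gate, False, detail))
        result.exclusion_reasons.append(reason)
        return result

    # time zero is located first so eligibility can use the index stay's
    # admission for the age computation; the gates are still *reported*
    # in protocol order (eligibility before time zero)
    icu_stays = [s for s in stays if s.unit_class == UnitClass.icu]
    time_zero, mode, index_stay = find_time_zero(vents, stays, cfg)
    age_stay = index_stay if index_stay is not None else (icu_stays[0] if icu_stays else None)

    eligible, reason = check_eligibility(patient, age_stay)
    if not eligible:
        return fail("eligibility", reason)
    result.trace.append(GateRecord("eligibility", True))

    if time_zero is None:
        return fail("time_zero", ExclusionReason.no_time_zero, "no ICU PEEP >= threshold")
    result.time_zero = time_zero
    result.vent_mode = mode
    result.trace.append(GateRecord("time_zero", True, f"time_zero={time_zero.isoformat()}"))

    pfs = build_pf_measurements(
        store.blood_gas_for(patient_id), store.vitals_fio2_for(patient_id), cfg
    )
    qpf = qualifying_pf(pfs, time_zero, cfg)
    if qpf is None:
        return fail(
            "qualifying_pf", ExclusionReason.no_qualifying_pf,
            f"{len(pfs)} P/F measurements, none <= {cfg.pf_threshold:g} after time zero",
        )
    result.qualifying_pf = qpf
    result.trace.append(GateRecord("qualifying_pf", True, f"worst ratio {qpf.ratio:.1f}"))

    reports = store.radiology_for(patient_id)
    if not positive_cxr_near(reports, time_zero, cfg):
        return fail("positive_cxr", ExclusionReason.no_positive_cxr)
    result.trace.append(GateRecord("positive_cxr", True))

    if fibrosis_excluded(store.comorbidities_for(patient_id)):
        return fail("no_fibrosis", ExclusionReason.fibrosis)
    result.trace.append(GateRecord("no_fibrosis", True))

    dur = invasive_vent_duration(vents, cfg)
    if dur < cfg.min_vent_duration:
        return fail(
            "vent_duration", ExclusionReason.vent_under_min, f"{dur:.1f} h invasive"
        )
    result.trace.append(GateRecord("vent_duration", True, f"{dur:.1f} h invasive"))

    risks = find_risk_factors(
        store.risk_factors_for(patient_id), index_stay.admit_ts, cfg
    )
    if not risks:
        return fail("risk_factor", ExclusionReason.no_risk_factor)
    result.trace.append(
        GateRecord("risk_factor", True, ";".join(sorted(r.value for r in risks)))
    )

    excluded, cardio_reasons = cardiogenic_excluded(
        store.cardiac_events_for(patient_id),
        store.ecg_for(patient_id),
        index_stay,
        time_zero,
        cfg,
    )
    if excluded:
        return fail("non_cardiogenic", ExclusionReason.cardiogenic, ";".join(cardio_reasons))
    result.trace.append(GateRecord("non_cardiogenic", True))

    result.ards = True
    result.severity = grade_severity(qpf.ratio)
    return result


def screen_cohort(
    store: EhrStore, cfg: Optional[ScreenConfig] = None
) -> list[ScreenResult]:
    """Screen every patient in deterministic patient_id order."""
    cfg = cfg or ScreenConfig()
    results = [screen_patient(store, pid, cfg) for pid in store.patient_ids]
    counts = funnel_counts(results)
    logger.info(
        "screened %d patients: %s",
        len(results),
        ", ".join(f"{g}={n}" for g, n in counts.items()),
    )
    return results


def funnel_counts(results: Sequence[ScreenResult]) -> dict[str, int]:
    """Patients surviving each sequential gate (monotone non-increasing)."""
    counts: dict[str, int] = {"screened": len(results)}
    for gate in GATE_ORDER:
        counts[gate] = sum(
            1
            for r in results
            if any(g.name == gate and g.passed for g in r.trace)
        )
    counts["ards"] = sum(1 for r in results if r.ards)
    return counts
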