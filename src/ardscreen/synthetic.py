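"""Seeded generator of labeled synthetic ICU-EHR cohorts.

Each patient is generated from an *archetype*: a template that either
satisfies every gate of the Berlin screen (a clean ARDS course) or
violates exactly one named gate (no PEEP >= 5, all P/F ratios > 300,
unilateral imaging, no risk factor, ventilation under 12 h, lung fibrosis
on the problem list, a cardiogenic exclusion).  On top of these, edge-case
archetypes reproduce the documented failure modes of retrospective
EHR screening: gold-positive patients whose *data* defeat the algorithm
(blood gases and chest films absent from the extract; sepsis onset more
than 72 h after ICU admission; home BiPAP with no charted PEEP) and a
gold-negative "cardiogenic mimic" whose adjudication relied on notes the
structured extract does not carry, producing a false positive.

Determinism: one RNG stream per cohort, split per patient by counter
(``SeedSequence([seed, patient_index])``), so a patient's rows depend only
on the seed, the index and the archetype.  All timestamps sit on a
1-minute grid inside a 30-day admission window.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ehr_model import (
    ComorbidityCategory,
    EhrStore,
    RiskFactorCategory,
    write_store,
)
from .screen import ExclusionReason

_WINDOW_START = pd.Timestamp("2016-03-01T00:00:00+00:00")
_WINDOW_DAYS = 30

_VENT_MODES = ["AC/VC", "SIMV", "PRVC", "PS"]

_BENIGN_CHARLSON = [
    c.value for c in ComorbidityCategory
    if c not in (ComorbidityCategory.ipf, ComorbidityCategory.ild,
                 ComorbidityCategory.pulmonary_fibrosis)
]
_FIBROSIS_VALUES = [
    ComorbidityCategory.ipf.value,
    ComorbidityCategory.ild.value,
    ComorbidityCategory.pulmonary_fibrosis.value,
]

_POSITIVE_PHRASES = [
    "bilateral infiltrates",
    "bilateral opacities",
    "bilateral interstitial edema",
    "bilateral patchy airspace infiltrates",
    "bilateral alveolar opacities",
    "bilateral hazy opacities",
]

_DISTRACTOR_SENTENCES = [
    "Lines and tubes in standard position",
    "No pneumothorax",
    "Heart size within normal limits",
    "Comparison with prior radiograph",
    "Endotracheal tube 4 cm above the carina",
]

_NEGATIVE_REPORTS = [
    "Right lower lobe infiltrate. Left lung clear.",
    "Bilateral pleural effusions. No focal consolidation.",
    "Clear lungs. No acute cardiopulmonary process.",
    "Left basilar atelectasis. Mild cardiomegaly.",
    "Low lung volumes. No focal airspace disease.",
]

_BENIGN_ECG = [
    "Sinus rhythm. Nonspecific findings.",
    "Sinus tachycardia. Normal intervals.",
    "Atrial fibrillation with controlled ventricular response.",
]


class Archetype(str, Enum):
    # gold-positive
    ards_clean = "ards_clean"
    missing_pf_and_cxr = "missing_pf_and_cxr"
    late_sepsis = "late_sepsis"
    home_bipap_no_peep = "home_bipap_no_peep"
    # gold-negative
    no_peep = "no_peep"
    pf_above_300 = "pf_above_300"
    unilateral_cxr = "unilateral_cxr"
    no_risk_factor = "no_risk_factor"
    short_vent = "short_vent"
    fibrosis_mimic = "fibrosis_mimic"
    cardiogenic_excluded = "cardiogenic_excluded"
    cardiogenic_mimic = "cardiogenic_mimic"


POSITIVE_ARCHETYPES = frozenset(
    {
        Archetype.ards_clean,
        Archetype.missing_pf_and_cxr,
        Archetype.late_sepsis,
        Archetype.home_bipap_no_peep,
    }
)

# what the screen should conclude for each archetype, by construction
EXPECTED_SCREEN_POSITIVE = frozenset(
    {Archetype.ards_clean, Archetype.cardiogenic_mimic}
)
EXPECTED_PRIMARY_REASON = {
    Archetype.no_peep: ExclusionReason.no_time_zero,
    Archetype.pf_above_300: ExclusionReason.no_qualifying_pf,
    Archetype.unilateral_cxr: ExclusionReason.no_positive_cxr,
    Archetype.no_risk_factor: ExclusionReason.no_risk_factor,
    Archetype.short_vent: ExclusionReason.vent_under_min,
    Archetype.fibrosis_mimic: ExclusionReason.fibrosis,
    Archetype.cardiogenic_excluded: ExclusionReason.cardiogenic,
    Archetype.missing_pf_and_cxr: ExclusionReason.no_qualifying_pf,
    Archetype.late_sepsis: ExclusionReason.no_risk_factor,
    Archetype.home_bipap_no_peep: ExclusionReason.no_time_zero,
}

# edge-case knobs exposed on the cohort spec; the rest of the negative
# pool is cycled deterministically
class EdgeCase(str, Enum):
    missing_pf_and_cxr = "missing_pf_and_cxr"
    late_sepsis = "late_sepsis"
    home_bipap_no_peep = "home_bipap_no_peep"
    cardiogenic_mimic = "cardiogenic_mimic"
    fibrosis_mimic = "fibrosis_mimic"
    short_vent = "short_vent"
    unilateral_cxr = "unilateral_cxr"


_POSITIVE_EDGES = (
    EdgeCase.missing_pf_and_cxr,
    EdgeCase.late_sepsis,
    EdgeCase.home_bipap_no_peep,
)
_NEGATIVE_EDGES = (
    EdgeCase.cardiogenic_mimic,
    EdgeCase.fibrosis_mimic,
    EdgeCase.short_vent,
    EdgeCase.unilateral_cxr,
)

_NEGATIVE_POOL = [
    Archetype.no_peep,
    Archetype.pf_above_300,
    Archetype.unilateral_cxr,
    Archetype.no_risk_factor,
    Archetype.short_vent,
    Archetype.fibrosis_mimic,
    Archetype.cardiogenic_excluded,
]


class ChartingNoise(BaseModel):
    """Charting realism knobs.

    ``ts_jitter_minutes`` jitters imaging and risk-factor charting times
    (bounded so template margins always stay inside the screen's windows);
    ``vitals_fio2_rate`` is the probability that a blood gas carries no lab
    FiO2 and must be matched to a vital-sign FiO2 instead.
    """

    ts_jitter_minutes: int = Field(5, ge=0, le=60)
    vitals_fio2_rate: float = Field(0.3, ge=0, le=1)


class SyntheticCohortSpec(BaseModel):
    """Prevalence, size, seed and edge-case injection rates for a cohort."""

    n_patients: int = Field(..., gt=0)
    ards_prevalence: float = Field(..., ge=0, le=1)
    seed: int = Field(..., ge=0)
    edge_case_rates: dict[EdgeCase, float] = Field(default_factory=dict)
    charting_noise: ChartingNoise = Field(default_factory=ChartingNoise)

    @model_validator(mode="after")
    def _check_rates(self):
        if any(not (0 <= r <= 1) for r in self.edge_case_rates.values()):
            raise ValueError("edge-case rates must be in [0, 1]")
        if sum(self.edge_case_rates.values()) > 1 + 1e-12:
            raise ValueError("edge-case rates must sum to at most 1")
        return self


@dataclass(frozen=True)
class GoldLabel:
    patient_id: str
    ards: bool
    archetype: str


# ---------------------------------------------------------------------------
# Row builders
# ---------------------------------------------------------------------------


def _minutes(m: int) -> pd.Timedelta:
    return pd.Timedelta(minutes=int(m))


def _iso(ts: pd.Timestamp) -> str:
    return ts.isoformat()


def generate_report_text(positive: bool, rng: np.random.Generator) -> str:
    """A short chest X-ray narrative; qualifying bilateral phrase iff positive."""
    if not positive:
        return str(rng.choice(_NEGATIVE_REPORTS))
    phrase = str(rng.choice(_POSITIVE_PHRASES))
    lead, tail = rng.choice(_DISTRACTOR_SENTENCES, size=2, replace=False)
    finding = phrase.capitalize() + str(rng.choice([" are present", " persist", ""]))
    return f"{lead}. {finding}. {tail}."


def _gen_patient(
    pid: str,
    archetype: Archetype,
    rng: np.random.Generator,
    noise: ChartingNoise,
) -> dict[str, list[dict]]:
    """Generate all EHR rows for one patient as CSV-dialect strings."""
    rows: dict[str, list[dict]] = {name: [] for name in (
        "patients", "icu_stays", "vent_settings", "blood_gas", "vitals_fio2",
        "radiology", "comorbidities", "risk_factors", "cardiac_events", "ecg",
    )}

    def jitter() -> int:
        j = noise.ts_jitter_minutes
        return int(rng.integers(-j, j + 1)) if j else 0

    admit = _WINDOW_START + _minutes(rng.integers(0, _WINDOW_DAYS * 24 * 60))
    stay_h = int(rng.integers(5 * 24, 14 * 24))
    discharge = admit + _minutes(stay_h * 60)
    age = int(rng.integers(25, 85))
    birth = (admit - pd.Timedelta(days=365 * age + 200)).date()

    rows["patients"].append(
        {"patient_id": pid, "birth_date": birth.isoformat(),
         "research_authorization": "true"}
    )
    rows["icu_stays"].append(
        {"patient_id": pid, "admit_ts": _iso(admit), "discharge_ts": _iso(discharge),
         "unit_class": "icu"}
    )

    tz = admit + _minutes(int(rng.integers(2 * 60, 25 * 60)))

    # --- ventilator course ------------------------------------------------
    if archetype is not Archetype.home_bipap_no_peep:
        if archetype is Archetype.short_vent:
            vent_h = int(rng.integers(4, 11))
        else:
            vent_h = int(rng.integers(24, 73))
        low_peep = archetype is Archetype.no_peep
        # a pre-intubation record that never qualifies as time zero
        rows["vent_settings"].append(
            {"patient_id": pid, "ts": _iso(tz - _minutes(120)),
             "peep": str(int(rng.integers(0, 5))), "mode": "",
             "invasive": "false", "location_class": "icu"}
        )
        for h in range(vent_h + 1):
            peep = int(rng.integers(0, 5)) if low_peep else int(rng.integers(5, 16))
            rows["vent_settings"].append(
                {"patient_id": pid, "ts": _iso(tz + _minutes(60 * h)),
                 "peep": str(peep), "mode": str(rng.choice(_VENT_MODES)),
                 "invasive": "true", "location_class": "icu"}
            )

    # --- blood gases / FiO2 ----------------------------------------------
    if archetype is not Archetype.missing_pf_and_cxr:
        if archetype is Archetype.pf_above_300:
            ratio = float(rng.uniform(320, 450))
            fio2 = float(rng.choice([0.3, 0.4, 0.5]))
        else:
            stratum = str(rng.choice(["mild", "moderate", "severe"], p=[0.4, 0.4, 0.2]))
            lo, hi = {"mild": (202, 298), "moderate": (102, 198),
                      "severe": (45, 98)}[stratum]
            ratio = float(rng.uniform(lo, hi))
            fio2 = float(rng.choice([0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]))
        pao2 = round(ratio * fio2, 1)
        gas_ts = tz + _minutes(int(rng.integers(30, 12 * 60)))
        use_vitals = rng.random() < noise.vitals_fio2_rate
        rows["blood_gas"].append(
            {"patient_id": pid, "ts": _iso(gas_ts), "pao2": f"{pao2:.1f}",
             "fio2_lab": "" if use_vitals else f"{fio2:.2f}"}
        )
        if use_vitals:
            rows["vitals_fio2"].append(
                {"patient_id": pid, "ts": _iso(gas_ts + _minutes(rng.integers(-10, 11))),
                 "fio2": f"{fio2:.2f}"}
            )
        # a second, better gas later in the course (never the worst ratio)
        pao2_2 = round(min(ratio + float(rng.uniform(15, 60)), 460) * fio2, 1)
        rows["blood_gas"].append(
            {"patient_id": pid, "ts": _iso(gas_ts + _minutes(240)),
             "pao2": f"{pao2_2:.1f}", "fio2_lab": f"{fio2:.2f}"}
        )
        # pre-admission gas on room air, never qualifying (before time zero)
        rows["blood_gas"].append(
            {"patient_id": pid, "ts": _iso(tz - _minutes(90)), "pao2": "90.0",
             "fio2_lab": "0.21"}
        )
        # distractor vital-sign FiO2 far from any gas draw
        rows["vitals_fio2"].append(
            {"patient_id": pid, "ts": _iso(admit + _minutes(60)), "fio2": "0.21"}
        )

    # --- imaging ----------------------------------------------------------
    if archetype is not Archetype.missing_pf_and_cxr:
        positive_film = archetype is not Archetype.unilateral_cxr
        cxr_ts = tz + _minutes(int(rng.integers(-6 * 60, 6 * 60 + 1)) + jitter())
        rows["radiology"].append(
            {"patient_id": pid, "ts": _iso(cxr_ts), "modality": "chest_xray",
             "report_text": generate_report_text(positive_film, rng)}
        )
        # a later film well outside the window, always non-qualifying
        rows["radiology"].append(
            {"patient_id": pid, "ts": _iso(tz + _minutes(30 * 60 + jitter())),
             "modality": "chest_xray",
             "report_text": generate_report_text(False, rng)}
        )

    # --- comorbidities ----------------------------------------------------
    if rng.random() < 0.5:
        for cat in rng.choice(_BENIGN_CHARLSON, size=rng.integers(1, 3), replace=False):
            rows["comorbidities"].append(
                {"patient_id": pid, "category": str(cat),
                 "recorded_ts": _iso(admit - pd.Timedelta(days=int(rng.integers(30, 1000))))}
            )
    if archetype is Archetype.fibrosis_mimic:
        rows["comorbidities"].append(
            {"patient_id": pid, "category": str(rng.choice(_FIBROSIS_VALUES)),
             "recorded_ts": _iso(admit - pd.Timedelta(days=int(rng.integers(30, 1000))))}
        )

    # --- risk factors -----------------------------------------------------
    if archetype is Archetype.late_sepsis:
        rows["risk_factors"].append(
            {"patient_id": pid,
             "ts": _iso(admit + _minutes(int(rng.integers(80 * 60, 120 * 60)) + jitter())),
             "category": RiskFactorCategory.sepsis_septic_shock.value,
             "source": str(rng.choice(["diagnosis", "note"]))}
        )
    elif archetype is not Archetype.no_risk_factor:
        cat = RiskFactorCategory(rng.choice([c.value for c in RiskFactorCategory]))
        rows["risk_factors"].append(
            {"patient_id": pid,
             "ts": _iso(admit + _minutes(int(rng.integers(-24 * 60, 48 * 60)) + jitter())),
             "category": cat.value,
             "source": str(rng.choice(["diagnosis", "note"]))}
        )

    # --- cardiac / ECG ----------------------------------------------------
    if archetype is Archetype.cardiogenic_excluded:
        variant = int(rng.integers(0, 3))
        if variant == 0:
            cat = str(rng.choice(["cardiogenic_pulmonary_edema", "cardiogenic_shock",
                                  "adhf_positive"]))
            rows["cardiac_events"].append(
                {"patient_id": pid, "ts": _iso(tz + _minutes(6 * 60)), "category": cat}
            )
        elif variant == 1:
            cat = str(rng.choice(["cad_history", "chf_history"]))
            rows["cardiac_events"].append(
                {"patient_id": pid,
                 "ts": _iso(admit - pd.Timedelta(days=int(rng.integers(10, 500)))),
                 "category": cat}
            )
        else:
            text = str(rng.choice(["New ST-segment changes in anterior leads.",
                                   "New left bundle branch block.",
                                   "Sinus rhythm with new LBBB."]))
            rows["ecg"].append(
                {"patient_id": pid,
                 "ts": _iso(tz + _minutes(int(rng.integers(-20 * 60, 20 * 60 + 1)))),
                 "findings_text": text}
            )
    elif rng.random() < 0.6:
        rows["ecg"].append(
            {"patient_id": pid,
             "ts": _iso(tz + _minutes(int(rng.integers(-12 * 60, 12 * 60 + 1)))),
             "findings_text": str(rng.choice(_BENIGN_ECG))}
        )

    return rows


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def generate_from_archetypes(
    archetypes: Sequence[Archetype],
    seed: int,
    noise: Optional[ChartingNoise] = None,
    meta: Optional[dict] = None,
) -> tuple[EhrStore, list[GoldLabel]]:
    """Generate one patient per archetype, split-seeded by patient index."""
    noise = noise or ChartingNoise()
    all_rows: dict[str, list[dict]] = {}
    labels: list[GoldLabel] = []
    for i, arch in enumerate(archetypes):
        pid = f"P{i + 1:05d}"
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        rows = _gen_patient(pid, Archetype(arch), rng, noise)
        for table, rlist in rows.items():
            all_rows.setdefault(table, []).extend(rlist)
        labels.append(GoldLabel(pid, Archetype(arch) in POSITIVE_ARCHETYPES, Archetype(arch).value))
    from .ehr_model import TABLE_COLUMNS

    frames = {
        table: pd.DataFrame(all_rows.get(table, []), columns=TABLE_COLUMNS[table]).replace(
            "", pd.NA
        )
        for table in TABLE_COLUMNS
    }
    store = EhrStore.from_frames(frames, meta={"seed": int(seed), **(meta or {})})
    return store, labels


def _edge_counts(n_side: int, rates: dict[EdgeCase, float], edges, n_total: int):
    counts = {e: int(round(n_total * rates.get(e, 0.0))) for e in edges}
    if sum(counts.values()) > n_side:
        raise ValueError(
            f"infeasible edge-case rates: {sum(counts.values())} patients requested "
            f"on a side with only {n_side}"
        )
    return counts


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[EhrStore, list[GoldLabel]]:
    """Generate a labeled cohort per the spec; deterministic for fixed seed.

    Gold-positive count is ``round(n * prevalence)``; edge-case counts are
    ``round(n * rate)`` carved out of the matching side (gold-positive for
    the three miss modes, gold-negative for the mimics).  Remaining
    negatives cycle deterministically through the single-gate-violation
    pool so every gate is exercised.
    """
    n = spec.n_patients
    n_pos = int(round(n * spec.ards_prevalence))
    n_neg = n - n_pos
    pos_edges = _edge_counts(n_pos, spec.edge_case_rates, _POSITIVE_EDGES, n)
    neg_edges = _edge_counts(n_neg, spec.edge_case_rates, _NEGATIVE_EDGES, n)

    archetypes: list[Archetype] = []
    for edge, cnt in pos_edges.items():
        archetypes.extend([Archetype(edge.value)] * cnt)
    archetypes.extend([Archetype.ards_clean] * (n_pos - sum(pos_edges.values())))
    for edge, cnt in neg_edges.items():
        archetypes.extend([Archetype(edge.value)] * cnt)
    n_pool = n_neg - sum(neg_edges.values())
    archetypes.extend(_NEGATIVE_POOL[i % len(_NEGATIVE_POOL)] for i in range(n_pool))

    return generate_from_archetypes(
        archetypes, spec.seed, spec.charting_noise,
        meta={"spec": spec.model_dump(mode="json")},
    )


# ---------------------------------------------------------------------------
# Purposeful-sampling style study cohorts
# ---------------------------------------------------------------------------

# composition: (clean positives, positive-miss edges, negative edges, n)
STUDY_COHORTS = {
    "derivation1": dict(
        n=50,
        positives={Archetype.ards_clean: 21, Archetype.missing_pf_and_cxr: 1,
                   Archetype.late_sepsis: 1},
        negatives={},
    ),
    "derivation2": dict(
        n=50,
        positives={Archetype.ards_clean: 20, Archetype.missing_pf_and_cxr: 1,
                   Archetype.late_sepsis: 1},
        negatives={},
    ),
    "validation": dict(
        n=50,
        positives={Archetype.ards_clean: 17, Archetype.missing_pf_and_cxr: 1},
        negatives={Archetype.cardiogenic_mimic: 1},
    ),
}


def purposeful_cohort(
    kind: str, seed: int, noise: Optional[ChartingNoise] = None
) -> tuple[EhrStore, list[GoldLabel]]:
    """A 50-patient enriched study-style cohort with staged failure modes.

    ``derivation1`` carries 23 gold positives of which two are screen
    misses (missing P/F & CXR; late sepsis); ``derivation2`` the same with
    22 gold positives; ``validation`` 18 gold positives with one
    missing-data miss plus one cardiogenic mimic that the screen falsely
    flags — the unique integer table consistent with the published
    validation percentages.
    """
    if kind not in STUDY_COHORTS:
        raise ValueError(f"unknown cohort kind {kind!r}; choose from {sorted(STUDY_COHORTS)}")
    comp = STUDY_COHORTS[kind]
    archetypes: list[Archetype] = []
    for arch, cnt in comp["positives"].items():
        archetypes.extend([arch] * cnt)
    for arch, cnt in comp["negatives"].items():
        archetypes.extend([arch] * cnt)
    n_pool = comp["n"] - len(archetypes)
    archetypes.extend(_NEGATIVE_POOL[i % len(_NEGATIVE_POOL)] for i in range(n_pool))
    return generate_from_archetypes(archetypes, seed, noise, meta={"cohort": kind})


# ---------------------------------------------------------------------------
# Gold-label I/O
# ---------------------------------------------------------------------------


def write_gold(labels: Sequence[GoldLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"patient_id": l.patient_id, "ards": "true" if l.ards else "false",
             "archetype": l.archetype}
            for l in labels
        ]
    ).to_csv(path, index=False)


def read_gold(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype="string", keep_default_na=False)
    for col in ("patient_id", "ards"):
        if col not in df.columns:
            raise ValueError(f"gold file {path} missing column '{col}'")
    return df


def write_cohort(
    store: EhrStore, labels: Sequence[GoldLabel], out_dir: str | Path
) -> None:
    """Write the ten-table CSV store plus gold.csv to a directory."""
    out_dir = Path(out_dir)
    write_store(store, out_dir)
    write_gold(labels, out_dir / "gold.csv")
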