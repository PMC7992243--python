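# Methods

## The phenotype

`ardscreen` implements a deterministic, retrospective computable
phenotype for ARDS following the Berlin definition: acute hypoxemia
(PaO₂/FiO₂ ≤ 300 with PEEP ≥ 5 cm H₂O), bilateral opacities on chest
imaging, a predisposing risk factor, and edema not explained by cardiac
failure. It operates on structured EHR extracts only — flowsheets,
labs, problem lists, report text — and is explicitly *not* a real-time
detector: it assumes the admission is complete and charted.

The screen is a sequence of boolean gates evaluated in a fixed order
with short-circuiting; the first failing gate is the patient's recorded
exclusion reason, and the trace keeps every gate that was evaluated so
that any verdict can be reproduced gate by gate. The non-short-circuit
evaluation of all gates yields the same verdict (this is enforced by an
oracle-equivalence test against an independent exhaustive evaluator).

## Anchors and windows

Everything downstream hangs off **time zero**, the first PEEP ≥ 5 cm H₂O
charted in an ICU area during an ICU stay. Choices that the underlying
clinical procedure leaves open, and how this implementation resolves
them:

- **Index stay** — the first ICU stay that yields a time zero ("first
  PEEP ≥ 5" governs). If no stay yields one, the patient is negative
  with reason `no_time_zero`; age for the eligibility gate then uses the
  first ICU stay.
- **Chest X-ray window** — "within 12 h" is anchored at time zero and
  applied symmetrically (± 12 h). Time zero is the only named anchor,
  and the symmetric reading is the permissive one; the window is
  configurable for sensitivity analyses.
- **Qualifying P/F** — must be at or after time zero. The Berlin
  criterion requires PEEP ≥ 5 *during* the P/F determination, but
  charting frequency cannot establish simultaneity, so time-zero
  precedence is the proxy. Severity grades the **minimum** (worst)
  qualifying ratio — the conservative clinical convention; the ratio
  used is recorded in the result.
- **Risk-factor window** — ± 72 h around ICU admission, configurable.
  The 72 h figure follows from the documented miss mode (sepsis arising
  beyond 72 h after admission escapes the search); the symmetric window
  admits pre-admission diagnoses such as trauma on arrival.
- **FiO₂ matching** — lab FiO₂ on the same blood-gas result wins;
  otherwise the nearest vital-sign FiO₂ within ± 15 min, ties broken
  toward the *earlier* record (deterministic, and pre-draw settings
  better reflect the gas-draw condition).
- **Ventilation duration** — published duration algorithms are
  charting-system-specific; here, invasive records with inter-record
  gaps ≤ 1 h merge into episodes, durations are last-minus-first per
  episode, summed, with inclusion at ≥ 12 h (boundary passes). A single
  isolated record contributes zero.
- **Severity boundaries** — severe < 100 ≤ moderate < 200 ≤ mild ≤ 300;
  ratios outside (0, 300] are a contract violation, not a stratum.

## Text matching

Radiology positivity is lowercase stem + proximity matching: within a
period-delimited sentence, a token starting with `bilateral` at most 3
tokens (configurable) before a token stemming to
infiltrate/opacity/opacification/edema. There is **no negation or
uncertainty handling** — "no bilateral infiltrates" is a (known) false
match class; this mirrors keyword-combination screening and is listed as
a limitation. "Bilateral pleural effusions" is deliberately not a match
(effusion is not a qualifying finding). The ECG matcher accepts "new
ST(-segment) changes/elevation/depression", "left bundle branch block"
and the abbreviation LBBB, case-insensitive.

## Units, timestamps, dirty rows

FiO₂ accepts fractions [0.21, 1.0] or percentages [21, 100] (divided by
100); values in (1.0, 21) are ambiguous between the two conventions and
are rejected rather than guessed — a silent misread would corrupt every
ratio. Exactly 21 is read as percent (the physical floor). Timestamps
are ISO-8601 normalized to UTC; naive timestamps are assumed UTC with a
logged count. Rows violating an invariant (non-positive PaO₂,
sub-physiological FiO₂, unparseable timestamps, overlapping ICU stays,
orphan patient ids) are dropped and counted per table, never fatal —
mirroring real extract dirtiness while keeping the pipeline runnable.
Missing *files* or *columns* are fatal.

## Diagnostic metrics

Sensitivity, specificity, PPV and NPV are percentages rounded **half-up**
to one decimal, matching the display convention of published validation
tables (31/32 = 96.875 → 96.9; banker's rounding would print 96.8 and
break cross-checks). Zero-denominator metrics are explicitly undefined
(`None`), never coerced. `reconstruct_tables` enumerates all integer 2×2
tables of a given n against fixed cells and/or target metrics at
one-decimal precision; on n = 50 the enumeration (≤ 23,426 tables) runs
in well under a second. It doubles as a consistency check on published
numbers: a cohort narrative of "two errors, both false negatives" is
arithmetically incompatible with a printed specificity below 100%, and
the enumeration returns the empty set for that constraint combination.

## The synthetic generator

The generator emulates a single-ICU-stay admission per patient inside a
30-day study window, timestamps on a 1-minute grid (avoiding sub-minute
tie ambiguity in nearest matching). Archetypes:

- **ards_clean** — every gate satisfied: PEEP 5–15 hourly in the ICU,
  24–72 h invasive ventilation, worst P/F drawn from the mild (202–298),
  moderate (102–198) or severe (45–98) stratum at 40/40/20%, a positive
  bilateral-keyword film within ± 6 h of time zero, one risk factor
  within ± 24/48 h of admission, no cardiac rows.
- Seven single-violation negatives (no PEEP ≥ 5; all ratios > 300;
  unilateral film; no risk factor; < 12 h ventilation; fibrosis on the
  problem list; a cardiogenic exclusion via acute event, history or ECG).
- Three **gold-positive miss archetypes** reproducing documented EHR
  failure modes: blood gases and chest films absent from the extract;
  sepsis onset 80–120 h after admission; home BiPAP with no charted
  ventilator rows.
- One **gold-negative false-positive archetype** (`cardiogenic_mimic`):
  structurally indistinguishable from a clean ARDS course because the
  cardiogenic adjudication lives in notes the extract does not carry.

Gold labels are assigned by construction (the archetype *is* the
adjudication). Charting noise jitters imaging/risk-factor times by up to
± 5 min (bounded at ± 60 so template margins never cross a window
boundary) and routes ~30% of blood gases through the vital-sign FiO₂
matching path instead of a lab FiO₂. Determinism: one RNG per patient
via `SeedSequence([seed, index])`, so growing a cohort never perturbs
existing patients, and regenerating with the same seed is byte-identical
on disk.

What the generator does **not** emulate — realistic vitals waveforms,
disease progression, demographic structure, negated report language,
multi-stay hospitalizations — bounds what passing tests show: they
validate the *algorithmic contract* (each gate fires exactly when its
criterion holds, misses happen exactly where data are structurally
absent), not performance on real clinical text or charting patterns.

`purposeful_cohort` stages enriched 50-patient study-style cohorts
(derivation 1: 23 gold positives with 2 staged misses; derivation 2:
22 with 2; validation: 18 with 1 miss plus 1 cardiogenic mimic). These
compositions are the unique integer tables recoverable from the printed
summary constraints, so the staged pipeline reproduces the published
percentages exactly for any seed.

## Problem sizes

The test suite screens cohorts up to 1,000 patients across five seeds
for clean-label recovery, 200 independent 20-patient stores for oracle
equivalence, and 1,000 random tables for metric consistency; the
acceptance script uses the same sizes. These are comfortable margins
for the properties being checked: recovery is exact by construction, so
more patients only re-demonstrate the same archetypes.

## Known limitations

- Keyword matching has no negation/uncertainty handling.
- The ventilation-duration rule is an episode-merge approximation, not a
  validated duration algorithm.
- The cardiogenic gate uses structured flags and ECG text only; Berlin's
  objective (echocardiographic) assessment is out of scope.
- One-sided vs. two-sided readings of the imaging and risk-factor
  windows are design choices, exposed as configuration rather than fixed
  facts.
- No ICD-code mapping, FHIR/OMOP connectivity, or real-time operation.
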