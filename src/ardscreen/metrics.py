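"""Diagnostic-accuracy arithmetic against a gold-standard adjudication.

Sensitivity, specificity, PPV and NPV are reported as percentages rounded
half-up to one decimal (display convention of published validation
tables); a metric whose denominator is zero is explicitly undefined
(``None``), never silently 0 or 100.

:func:`reconstruct_tables` inverts the reporting direction: given a cohort
size and any combination of fixed cell counts and target one-decimal
metrics, it enumerates every non-negative integer 2x2 table consistent
with them.  This is the oracle used to recover the integer confusion
tables behind published summary percentages and to prove their uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from .errors import ArdscreenError, KeyMismatchError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages in [0, 100] rounded to one decimal; None = undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (96.875 -> 96.9), not banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(
    pred: Mapping[str, bool], gold: Mapping[str, bool]
) -> ConfusionMatrix:
    """2x2 table from per-patient predicted and gold-standard verdicts.

    The two maps must cover exactly the same patients; a mismatch is fatal
    and lists the differing ids.
    """
    pred_keys, gold_keys = set(pred), set(gold)
    if pred_keys != gold_keys:
        raise KeyMismatchError(pred_keys - gold_keys, gold_keys - pred_keys)
    tp = fp = fn = tn = 0
    for pid in pred_keys:
        p, g = bool(pred[pid]), bool(gold[pid])
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio_pct(num: int, den: int) -> Optional[float]:
    if den == 0:
        return None
    return round_half_up(100.0 * num / den)


def diagnostics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV (percent, one decimal, half-up)."""
    if cm.n == 0:
        raise ArdscreenError("cannot compute diagnostics on an empty table")
    return DiagnosticMetrics(
        sensitivity=_ratio_pct(cm.tp, cm.tp + cm.fn),
        specificity=_ratio_pct(cm.tn, cm.tn + cm.fp),
        ppv=_ratio_pct(cm.tp, cm.tp + cm.fp),
        npv=_ratio_pct(cm.tn, cm.tn + cm.fn),
    )


def reconstruct_tables(
    n: int,
    fixed: Optional[Mapping[str, int]] = None,
    targets: Optional[Mapping[str, float]] = None,
) -> list[ConfusionMatrix]:
    """All integer 2x2 tables of size ``n`` matching counts and metrics.

    ``fixed`` pins individual cells (keys tp/fp/fn/tn); ``targets`` pins
    one-decimal-rounded metrics (keys sensitivity/specificity/ppv/npv).
    Matching is exact at one-decimal display precision.  An empty result
    is a valid outcome (the constraints are inconsistent).
    """
    if n <= 0 or n > 10_000:
        raise ValueError("n must be in 1..10000")
    fixed = dict(fixed or {})
    targets = dict(targets or {})
    unknown = set(fixed) - {"tp", "fp", "fn", "tn"}
    if unknown:
        raise ValueError(f"unknown fixed cells: {sorted(unknown)}")
    unknown = set(targets) - {"sensitivity", "specificity", "ppv", "npv"}
    if unknown:
        raise ValueError(f"unknown target metrics: {sorted(unknown)}")

    def cell_range(name: str, upper: int) -> range:
        if name in fixed:
            v = fixed[name]
            return range(v, v + 1) if 0 <= v <= upper else range(0)
        return range(upper + 1)

    out: list[ConfusionMatrix] = []
    for tp in cell_range("tp", n):
        for fp in cell_range("fp", n - tp):
            for fn in cell_range("fn", n - tp - fp):
                tn = n - tp - fp - fn
                if tn < 0 or ("tn" in fixed and tn != fixed["tn"]):
                    continue
                cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
                m = diagnostics(cm).as_dict()
                if all(
                    m[k] is not None and abs(m[k] - v) < 1e-9
                    for k, v in targets.items()
                ):
                    out.append(cm)
    return out
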