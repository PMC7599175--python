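"""Clinical metric bookkeeping: sensitivity, specificity, PPV, NPV.

Metrics are reported at two scopes. ``in_zone`` counts only the zone
members the ensemble actually classified. ``whole_dataset`` additionally
counts every step-1 non-member as predicted-normal — a delayed subject the
zone screen missed becomes a false negative, and each correctly screened-out
normal subject a true negative — so the two scopes differ exactly by the
screening step's own errors and savings.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .fnn_ensemble import DELAYED, EXCLUDED, NORMAL

IN_ZONE = "in_zone"
WHOLE_DATASET = "whole_dataset"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    scope: str = IN_ZONE

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.scope not in (IN_ZONE, WHOLE_DATASET):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The four screening metrics as fractions; ``None`` marks an undefined
    metric (zero denominator) — never silently 0 or 1."""

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    excluded_severe: bool = False

    def as_percent(self, name: str) -> str:
        """Metric formatted as a percentage with 1 decimal, half-up
        rounding (85.7%-style presentation); 'n/a' when undefined."""
        value = getattr(self, name)
        if value is None:
            return "n/a"
        q = (Decimal(value) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        return f"{q}%"

    def summary(self) -> dict[str, str]:
        return {m: self.as_percent(m)
                for m in ("sensitivity", "specificity", "ppv", "npv")}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def report_from_counts(counts: ConfusionCounts,
                       excluded_severe: bool = False) -> MetricReport:
    return MetricReport(
        counts=counts,
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        excluded_severe=excluded_severe,
    )


def score(predictions: Sequence[str], labels: Sequence[int],
          scope: str = IN_ZONE, excluded_severe: bool = False) -> MetricReport:
    """Confusion counts and metrics from aligned predictions and labels.

    ``predictions`` are ``"delayed"`` / ``"normal"`` /
    ``"excluded_incomplete"``; excluded subjects are removed before
    counting. At whole-dataset scope the caller has already mapped step-1
    non-members to ``"normal"``.
    """
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must be aligned")
    pairs = [(p, int(y)) for p, y in zip(predictions, labels) if p != EXCLUDED]
    if not pairs:
        raise ValueError(f"empty scope: no subjects to score in {scope}")
    bad = {p for p, _ in pairs} - {DELAYED, NORMAL}
    if bad:
        raise ValueError(f"unknown prediction values {sorted(bad)}")
    tp = sum(1 for p, y in pairs if p == DELAYED and y == 1)
    fp = sum(1 for p, y in pairs if p == DELAYED and y == 0)
    tn = sum(1 for p, y in pairs if p == NORMAL and y == 0)
    fn = sum(1 for p, y in pairs if p == NORMAL and y == 1)
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, scope=scope)
    return report_from_counts(counts, excluded_severe=excluded_severe)


def whole_from_zone(zone_counts: ConfusionCounts, missed_delayed: int,
                    outside_normals: int) -> ConfusionCounts:
    """Lift in-zone counts to whole-dataset scope.

    ``missed_delayed`` delayed subjects fell outside the zones (step-1
    false negatives); ``outside_normals`` non-delayed subjects were
    correctly screened out (true negatives).
    """
    if missed_delayed < 0 or outside_normals < 0:
        raise ValueError("missed_delayed and outside_normals must be >= 0")
    return ConfusionCounts(tp=zone_counts.tp, fp=zone_counts.fp,
                           tn=zone_counts.tn + outside_normals,
                           fn=zone_counts.fn + missed_delayed,
                           scope=WHOLE_DATASET)
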