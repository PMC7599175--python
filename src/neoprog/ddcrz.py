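"""Developmental-delay common relaxed zones (step 1 of the predictor).

The delayed class is rare (6–13% of a cohort), so the predictor first
screens with per-characteristic intervals built around the delayed training
subjects' values: for each selected characteristic the zone is the delayed
min–max hull dilated by a fraction of the pooled range on each side. A
subject whose values sit inside (enough of) the zones proceeds to the
network ensemble; a subject outside is called normally developed outright.
This cheap first step removes most of the majority class before any network
sees the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .ld_selection import SelectionResult
from .synthetic_cohort import CharacteristicDescriptor, CohortTable

#: fraction of the pooled range added on each side of the delayed hull
DEFAULT_RELAXATION = 0.10

MEMBER = "member"
NON_MEMBER = "non_member"
INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class RelaxedZoneSet:
    """Per-characteristic screening intervals plus the membership rule.

    ``membership_fraction`` is the fraction of zone characteristics a
    subject must satisfy to be a member (1.0 = every zone). ``n_train`` is
    the number of training subjects the zones were built from.
    """

    zones: Mapping[CharacteristicDescriptor, tuple[float, float]]
    relaxation: float
    membership_fraction: float = 1.0
    n_train: int = 0

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("no zone characteristics")
        if self.relaxation < 0:
            raise ValueError("relaxation must be >= 0")
        if not 0.0 < self.membership_fraction <= 1.0:
            raise ValueError("membership_fraction must be in (0, 1]")
        for char, (low, high) in self.zones.items():
            if not low < high:
                raise ValueError(f"zone for {char} has low >= high")

    @property
    def characteristics(self) -> list[CharacteristicDescriptor]:
        return sorted(self.zones.keys())


def build_ddcrz(table: CohortTable, selection: SelectionResult,
                relaxation: float = DEFAULT_RELAXATION,
                membership_fraction: float = 1.0) -> RelaxedZoneSet:
    """Build zones from the (training) table's delayed subjects.

    For each selected characteristic with pooled training range R the zone
    is [min(delayed) - relaxation*R, max(delayed) + relaxation*R]. Missing
    values are ignored per characteristic; every characteristic needs at
    least one delayed value.
    """
    if not selection.selected:
        raise ValueError("no zone characteristics: selection is empty")
    labels = table.labels
    zones: dict[CharacteristicDescriptor, tuple[float, float]] = {}
    for char in selection.selected:
        vals = table.values(char)
        present = np.isfinite(vals)
        dv = vals[present & (labels == 1)]
        av = vals[present]
        if dv.size == 0:
            raise ValueError(f"no delayed training values for {char}")
        r = float(av.max() - av.min())
        if r <= 0:
            raise ValueError(f"degenerate training range for {char}")
        zones[char] = (float(dv.min()) - relaxation * r,
                       float(dv.max()) + relaxation * r)
    return RelaxedZoneSet(zones=zones, relaxation=relaxation,
                          membership_fraction=membership_fraction,
                          n_train=len(table))


def zone_membership(subject_values: Mapping[CharacteristicDescriptor, float],
                    zones: RelaxedZoneSet) -> str:
    """Step-1 decision for one subject.

    Returns ``"incomplete"`` if any zone characteristic is missing (such
    subjects are excluded from the analysis set, mirroring missing-peak
    exclusions), ``"member"`` if the fraction of zone characteristics whose
    value lies inside its closed interval reaches ``membership_fraction``,
    else ``"non_member"``.
    """
    chars = zones.characteristics
    vals = []
    for char in chars:
        v = subject_values.get(char, np.nan)
        if v is None or not np.isfinite(v):
            return INCOMPLETE
        vals.append(float(v))
    inside = sum(1 for char, v in zip(chars, vals)
                 if zones.zones[char][0] <= v <= zones.zones[char][1])
    frac = inside / len(chars)
    return MEMBER if frac >= zones.membership_fraction - 1e-12 else NON_MEMBER
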