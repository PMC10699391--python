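"""Classical test theory: item facility, the facility-axis map variant, and
FSEP practitioner-level score bands.

Facility is the percentage of counted respondents answering an item
correctly — the CTT difficulty proxy.  A map can be drawn on a 0-100
facility axis instead of logits; the axis is inverted (100 - facility) so
that, as on the logit map, harder items sit higher.

Practitioner levels are the FSEP score bands hospitals use as role-specific
requirements: level 1 spans 55-65% and level 3 requires strictly more than
75%.  Level 2 fills the gap (65, 75]; below 55 is level 0 (not yet level 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DomainError, ResponseMatrix

__all__ = [
    "FacilityRecord",
    "LevelBands",
    "DEFAULT_LEVEL_BANDS",
    "facility",
    "facility_table",
    "facility_axis_position",
    "classify_practitioner_level",
]


@dataclass
class FacilityRecord:
    item_id: str
    facility: float  # percentage in [0, 100]
    n_respondents: int


@dataclass(frozen=True)
class LevelBands:
    """Percentage boundaries of practitioner levels 0-3.

    Closure convention: level 1 is the closed band [l1_low, l1_high];
    level 2 is (l1_high, l3_low]; level 3 is strictly above l3_low.
    The bands partition [0, 100] with no gaps or overlaps.
    """

    l1_low: float = 55.0
    l1_high: float = 65.0
    l3_low: float = 75.0

    def __post_init__(self) -> None:
        if not 0 <= self.l1_low <= self.l1_high <= self.l3_low <= 100:
            raise DomainError("level bands must satisfy 0 <= l1_low <= l1_high <= l3_low <= 100")


DEFAULT_LEVEL_BANDS = LevelBands()


def facility(responses: ResponseMatrix, item_id: str) -> FacilityRecord:
    """Facility of one item: 100 * correct / counted respondents.

    Respondents whose cell is flagged missing are excluded from the
    denominator; with zero counted respondents the facility is undefined.
    """
    try:
        j = responses.item_ids.index(item_id)
    except ValueError:
        raise KeyError(f"item {item_id!r} not in response matrix") from None
    counted = ~responses.missing[:, j]
    n = int(counted.sum())
    if n == 0:
        raise DomainError(f"item {item_id!r}: zero counted respondents, facility undefined")
    correct = int((responses.scores[counted, j] >= responses.max_scores[j]).sum())
    return FacilityRecord(item_id=item_id, facility=100.0 * correct / n, n_respondents=n)


def facility_table(responses: ResponseMatrix) -> list[FacilityRecord]:
    return [facility(responses, iid) for iid in responses.item_ids]


def facility_axis_position(fac: float) -> float:
    """Vertical position on the percentage-difficulty axis: 100 - facility.

    Inverting facility makes the facility-axis map read like the logit map:
    higher means harder, so an item every respondent gets right sits at the
    bottom (position 0).
    """
    if not 0 <= fac <= 100:
        raise DomainError(f"facility {fac} outside [0, 100]")
    return 100.0 - fac


def classify_practitioner_level(score: float,
                                bands: LevelBands = DEFAULT_LEVEL_BANDS) -> int:
    """Practitioner level 0-3 for a percentage score."""
    if not 0 <= score <= 100:
        raise DomainError(f"score {score} outside [0, 100]")
    if score > bands.l3_low:
        return 3
    if score > bands.l1_high:
        return 2
    if score >= bands.l1_low:
        return 1
    return 0
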