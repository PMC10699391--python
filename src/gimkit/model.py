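"""Core data model: item banks, response tables, person estimates, map layouts.

Everything downstream (calibration, map building, rendering) consumes these
types.  They are deliberately plain dataclasses over numpy/pandas containers:
an :class:`ItemBank` is an ordered collection of items on a common logit
scale, a :class:`ResponseMatrix` is a candidates x items integer score
matrix, and a :class:`GimLayout` is the fully resolved per-candidate map.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Canonical FSEP subject clusters in display order: fetal heart rate
#: physiology, utero-placental function, the "normal" CTG, baseline rate and
#: variability, decelerations, maternal heart rate, uncommon patterns, and
#: the clinical guideline cluster.
CANONICAL_CLUSTERS: tuple[str, ...] = (
    "PHYS",
    "UPFH",
    "NORM",
    "BFHR",
    "DECEL",
    "MHR",
    "UNCOM",
    "RANZ",
)

MEAN_ZERO_TOL = 1e-8


class GimError(Exception):
    """Base class for all gimkit errors."""


class FormatError(GimError):
    """Malformed input file or record."""


class ValidationError(GimError):
    """Inputs parse but violate a model invariant."""


class DomainError(GimError):
    """Argument outside the mathematical domain of an operation."""


class CalibrationConstraint(str, enum.Enum):
    """How the logit scale origin is identified."""

    MEAN_ZERO = "mean_zero"
    ANCHORED = "anchored"


class BlankPolicy(str, enum.Enum):
    """Treatment of unanswered items when scoring raw option codes."""

    INCORRECT = "incorrect"
    MISSING = "missing"


class Side(str, enum.Enum):
    """Horizontal side of the map's central axis."""

    LEFT_CORRECT = "left_correct"
    RIGHT_INCORRECT = "right_incorrect"


class Quadrant(str, enum.Enum):
    UPPER_LEFT = "upper_left"
    UPPER_RIGHT = "upper_right"
    LOWER_LEFT = "lower_left"
    LOWER_RIGHT = "lower_right"


class SubjectFlag(str, enum.Enum):
    STRENGTH = "strength"
    WEAKNESS = "weakness"
    NONE = "none"


@dataclass
class ItemRecord:
    """A single bank item.

    ``difficulty`` is the Rasch location in logits (``None`` until the bank
    is calibrated or anchored); ``answer_key`` is the numbered option code of
    the correct answer; ``max_score`` is 1 for dichotomous items.
    """

    item_id: str
    subject_cluster: str
    answer_key: int = 1
    difficulty: Optional[float] = None
    max_score: int = 1

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be non-empty")
        if not self.subject_cluster:
            raise ValidationError(f"item {self.item_id!r}: subject_cluster must be non-empty")
        if self.max_score < 1:
            raise ValidationError(f"item {self.item_id!r}: max_score must be >= 1")
        if self.difficulty is not None and not math.isfinite(self.difficulty):
            raise ValidationError(f"item {self.item_id!r}: difficulty must be finite")


@dataclass
class ItemBank:
    items: list[ItemRecord]
    calibration_constraint: CalibrationConstraint = CalibrationConstraint.MEAN_ZERO

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate item_id {dup!r} in item bank")
        if (
            self.calibration_constraint is CalibrationConstraint.MEAN_ZERO
            and self.is_calibrated
            and len(self.items) > 0
        ):
            mean = float(np.mean([it.difficulty for it in self.items]))
            if abs(mean) > MEAN_ZERO_TOL:
                raise ValidationError(
                    f"mean-zero bank has difficulty mean {mean:.3e} (|mean| > {MEAN_ZERO_TOL:g})"
                )

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def is_calibrated(self) -> bool:
        return all(it.difficulty is not None for it in self.items)

    def difficulties(self) -> np.ndarray:
        if not self.is_calibrated:
            missing = [it.item_id for it in self.items if it.difficulty is None]
            raise ValidationError(f"bank not calibrated; items without difficulty: {missing}")
        return np.array([it.difficulty for it in self.items], dtype=float)

    def __getitem__(self, item_id: str) -> ItemRecord:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __len__(self) -> int:
        return len(self.items)

    def clusters(self) -> list[str]:
        """Distinct cluster labels in canonical display order.

        Labels drawn from the canonical FSEP set keep the published listing
        order; any others are appended alphabetically.
        """
        present = {it.subject_cluster for it in self.items}
        ordered = [c for c in CANONICAL_CLUSTERS if c in present]
        ordered += sorted(present - set(CANONICAL_CLUSTERS))
        return ordered


@dataclass
class RawResponseTable:
    """Raw option codes as sat: one row per candidate, one column per item.

    ``None`` entries are unanswered items; scoring policy decides their fate.
    """

    candidate_ids: list[str]
    item_ids: list[str]
    options: list[list[Optional[int]]]

    def __post_init__(self) -> None:
        if len(set(self.candidate_ids)) != len(self.candidate_ids):
            raise FormatError("duplicate candidate_id in response table")
        for row in self.options:
            if len(row) != len(self.item_ids):
                raise FormatError("ragged response table row")


@dataclass
class ResponseMatrix:
    """Scored candidate x item matrix; entries are integers in [0, max_score_i].

    ``missing`` marks cells excluded from facility denominators when blanks
    are treated as missing rather than incorrect.
    """

    candidate_ids: list[str]
    item_ids: list[str]
    scores: np.ndarray
    missing: Optional[np.ndarray] = None
    max_scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.shape != (len(self.candidate_ids), len(self.item_ids)):
            raise ValidationError(
                f"score matrix shape {self.scores.shape} inconsistent with "
                f"{len(self.candidate_ids)} candidates x {len(self.item_ids)} items"
            )
        if len(set(self.candidate_ids)) != len(self.candidate_ids):
            raise FormatError("duplicate candidate_id")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise FormatError("duplicate item_id")
        if self.max_scores is None:
            self.max_scores = np.ones(len(self.item_ids), dtype=int)
        self.max_scores = np.asarray(self.max_scores, dtype=int)
        if self.missing is None:
            self.missing = np.zeros_like(self.scores, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if np.any(self.scores < 0) or np.any(self.scores > self.max_scores[None, :]):
            raise ValidationError("scores outside per-item [0, max_score] range")

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def row(self, candidate_id: str) -> np.ndarray:
        try:
            idx = self.candidate_ids.index(candidate_id)
        except ValueError:
            raise KeyError(f"candidate {candidate_id!r} not in response matrix") from None
        return self.scores[idx]

    def raw_scores(self) -> np.ndarray:
        return self.scores.sum(axis=1)


@dataclass
class PersonEstimate:
    """Ability estimate for one candidate: raw score, logit ability, SE."""

    candidate_id: str
    raw_score: int
    ability: float
    standard_error: float
    n_administered: int


@dataclass
class PlacedItem:
    """One item positioned on a candidate's map."""

    item_id: str
    subject_cluster: str
    side: Side
    y: float
    quadrant: Optional[Quadrant] = None


@dataclass
class ClusterGroup:
    """Co-located items sharing cluster and side within the linkage tolerance."""

    subject_cluster: str
    side: Side
    member_ids: list[str]
    y: float

    @property
    def count(self) -> int:
        return len(self.member_ids)

    @property
    def label(self) -> str:
        if self.count >= 2:
            return f"{self.subject_cluster} ({self.count})"
        return self.subject_cluster


@dataclass
class GimLayout:
    """A candidate's fully positioned Graphical Item Map."""

    candidate_id: str
    ability_line: float
    columns: list[str]
    placed: list[PlacedItem]
    groups: list[ClusterGroup]
    flags: dict[str, SubjectFlag]
    pass_line: Optional[float] = None

    def validate(self) -> None:
        grouped = [m for g in self.groups for m in g.member_ids]
        placed_ids = [p.item_id for p in self.placed]
        if sorted(grouped) != sorted(placed_ids):
            raise ValidationError("groups do not partition the placed items")
        if len(set(placed_ids)) != len(placed_ids):
            raise ValidationError("item placed more than once")
        if self.pass_line is not None:
            if any(p.quadrant is None for p in self.placed):
                raise ValidationError("pass line set but quadrants unassigned")

    def quadrant_counts(self) -> dict[Quadrant, int]:
        counts = {q: 0 for q in Quadrant}
        for p in self.placed:
            if p.quadrant is not None:
                counts[p.quadrant] += 1
        return counts


@dataclass
class LayoutConfig:
    """Tunable map-construction parameters.

    ``cluster_tolerance`` is the single-linkage co-location window in logits;
    ``weakness_min_count`` / ``strength_min_items`` drive subject flagging;
    ``pass_standard`` (logits) switches on quadrant assignment.
    """

    cluster_tolerance: float = 0.15
    column_order: Optional[Sequence[str]] = None
    weakness_min_count: int = 2
    strength_min_items: int = 3
    pass_standard: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cluster_tolerance < 0:
            raise ValidationError("cluster_tolerance must be >= 0")
        if self.weakness_min_count < 1 or self.strength_min_items < 1:
            raise ValidationError("flag thresholds must be >= 1")


@dataclass
class SimulationSpec:
    """Generative settings for synthetic response matrices."""

    n_persons: int
    difficulties: np.ndarray
    ability_mean: float = 0.5
    ability_sd: float = 1.0
    seed: int = 0
    model: str = "rasch"

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        if self.ability_sd < 0:
            raise ValidationError("ability_sd must be >= 0")
        self.difficulties = np.asarray(self.difficulties, dtype=float)
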