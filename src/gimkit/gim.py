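"""Construction of one candidate's Graphical Item Map.

The map places every administered item by three coordinates: subject-cluster
column, vertical difficulty (logits, higher = harder), and side of the
central axis (left if the candidate answered it correctly, right if not).
Items of similar difficulty within one (cluster, side) cell are co-located
into a labelled group, "CLUSTER (n)".  A horizontal line marks the
candidate's ability; an optional second line marks the pass standard and
splits the map into four quadrants — the lower-right quadrant (easy items
answered incorrectly) is the priority-revision zone.  Per-cluster
strength/weakness flags operationalise the hand-drawn ellipses of the
operational reports with a deterministic easy-miss counting rule.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import (
    ClusterGroup,
    GimLayout,
    ItemBank,
    LayoutConfig,
    PersonEstimate,
    PlacedItem,
    Quadrant,
    ResponseMatrix,
    Side,
    SubjectFlag,
    ValidationError,
)
from .rasch import invert_tcc

__all__ = [
    "place_items",
    "group_colocated",
    "assign_quadrants",
    "flag_subjects",
    "build_gim",
    "pass_standard_to_logits",
]


def place_items(scores: Sequence[int], item_ids: Sequence[str],
                bank: ItemBank) -> list[PlacedItem]:
    """Place each administered item left (correct) or right (incorrect) at
    its bank difficulty."""
    placed = []
    for iid, x in zip(item_ids, scores):
        rec = bank[iid]
        if rec.difficulty is None:
            raise ValidationError(f"item {iid!r} has no calibrated difficulty")
        side = Side.LEFT_CORRECT if int(x) >= rec.max_score else Side.RIGHT_INCORRECT
        placed.append(PlacedItem(item_id=iid, subject_cluster=rec.subject_cluster,
                                 side=side, y=float(rec.difficulty)))
    return placed


def group_colocated(placed: Sequence[PlacedItem],
                    config: Optional[LayoutConfig] = None) -> list[ClusterGroup]:
    """Single-linkage co-location within each (cluster, side) cell.

    Items sorted by difficulty are chained into one group while consecutive
    gaps stay within ``cluster_tolerance``; on a one-dimensional axis this
    chaining is exactly the transitive closure of the pairwise
    within-tolerance relation, so a chain 0.0, 0.1, 0.2 merges at tolerance
    0.15 even though its end-to-end span exceeds it.  Group height is the
    mean member difficulty.  Groups are returned sorted by (cluster, side,
    height).
    """
    config = config or LayoutConfig()
    tol = config.cluster_tolerance
    cells: dict[tuple[str, Side], list[PlacedItem]] = {}
    for p in placed:
        cells.setdefault((p.subject_cluster, p.side), []).append(p)
    groups: list[ClusterGroup] = []
    for (cluster, side), members in cells.items():
        members = sorted(members, key=lambda p: (p.y, p.item_id))
        chain = [members[0]]
        for p in members[1:]:
            if p.y - chain[-1].y <= tol:
                chain.append(p)
            else:
                groups.append(_make_group(cluster, side, chain))
                chain = [p]
        groups.append(_make_group(cluster, side, chain))
    groups.sort(key=lambda g: (g.subject_cluster, g.side.value, g.y))
    return groups


def _make_group(cluster: str, side: Side, members: list[PlacedItem]) -> ClusterGroup:
    return ClusterGroup(
        subject_cluster=cluster,
        side=side,
        member_ids=[p.item_id for p in members],
        y=float(np.mean([p.y for p in members])),
    )


def assign_quadrants(placed: Sequence[PlacedItem], pass_line: float) -> list[PlacedItem]:
    """Assign each placed item to one of the four pass/correct quadrants.

    The pass line and the correct/incorrect axis partition the map; an item
    exactly on the line falls in the lower quadrants (closed-below
    convention, keeping revision guidance conservative).
    """
    if not np.isfinite(pass_line):
        raise ValidationError("pass_line must be finite")
    out = []
    for p in placed:
        upper = p.y > pass_line
        if p.side is Side.LEFT_CORRECT:
            q = Quadrant.UPPER_LEFT if upper else Quadrant.LOWER_LEFT
        else:
            q = Quadrant.UPPER_RIGHT if upper else Quadrant.LOWER_RIGHT
        out.append(PlacedItem(p.item_id, p.subject_cluster, p.side, p.y, q))
    return out


def flag_subjects(placed: Sequence[PlacedItem], ability: float,
                  config: Optional[LayoutConfig] = None) -> dict[str, SubjectFlag]:
    """Per-cluster strength/weakness flags against the candidate's ability.

    Weakness: at least ``weakness_min_count`` items in the cluster answered
    incorrectly despite sitting at or below the candidate's ability (easy
    misses).  Strength: the cluster has at least ``strength_min_items``
    items, no easy misses, and at least one correct item harder than the
    candidate's ability.  Weakness takes precedence if both fire.  An item
    exactly at the ability line counts as "at or below".
    """
    config = config or LayoutConfig()
    clusters: dict[str, list[PlacedItem]] = {}
    for p in placed:
        clusters.setdefault(p.subject_cluster, []).append(p)
    flags: dict[str, SubjectFlag] = {}
    for cluster, items in clusters.items():
        easy_misses = sum(1 for p in items
                          if p.side is Side.RIGHT_INCORRECT and p.y <= ability)
        hard_hits = sum(1 for p in items
                        if p.side is Side.LEFT_CORRECT and p.y > ability)
        if easy_misses >= config.weakness_min_count:
            flags[cluster] = SubjectFlag.WEAKNESS
        elif (len(items) >= config.strength_min_items
              and easy_misses == 0 and hard_hits >= 1):
            flags[cluster] = SubjectFlag.STRENGTH
        else:
            flags[cluster] = SubjectFlag.NONE
    return flags


def pass_standard_to_logits(pass_standard, bank: ItemBank) -> float:
    """Resolve a pass standard given in logits, raw score, or "NN%".

    A string ending in "%" is a percentage of the maximum raw score and is
    converted through the inverse test characteristic curve of the bank.
    """
    if isinstance(pass_standard, str):
        s = pass_standard.strip()
        if s.endswith("%"):
            frac = float(s[:-1]) / 100.0
            target = frac * sum(it.max_score for it in bank.items)
            return invert_tcc(target, bank.difficulties())
        return float(s)
    return float(pass_standard)


def build_gim(candidate_id: str, responses: ResponseMatrix, bank: ItemBank,
              abilities: Sequence[PersonEstimate],
              config: Optional[LayoutConfig] = None) -> GimLayout:
    """Assemble the full map for one candidate.

    Pipeline: place items, co-locate groups, assign quadrants (when a pass
    standard is configured), flag subjects.  Columns follow the configured
    order, defaulting to the bank's canonical cluster order.  The result is
    fully deterministic in its inputs.
    """
    config = config or LayoutConfig()
    row = responses.row(candidate_id)  # KeyError if absent
    try:
        est = next(a for a in abilities if a.candidate_id == candidate_id)
    except StopIteration:
        raise KeyError(f"candidate {candidate_id!r} has no ability estimate") from None

    item_ids = responses.item_ids
    placed = place_items(row, item_ids, bank)
    pass_line = None
    if config.pass_standard is not None:
        pass_line = pass_standard_to_logits(config.pass_standard, bank)
        placed = assign_quadrants(placed, pass_line)
    groups = group_colocated(placed, config)
    flags = flag_subjects(placed, est.ability, config)

    if config.column_order is not None:
        columns = list(config.column_order)
    else:
        columns = bank.clusters()

    layout = GimLayout(
        candidate_id=candidate_id,
        ability_line=float(est.ability),
        columns=columns,
        placed=placed,
        groups=groups,
        flags=flags,
        pass_line=pass_line,
    )
    layout.validate()
    return layout
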