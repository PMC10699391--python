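"""Partial Credit Model category probabilities and category-level map placement.

For polytomous items scored 0..m, the PCM gives

    P(X = k) = exp( sum_{j<=k} (theta - delta_j) ) / normaliser,

with the empty sum for k = 0 and adjacent-category thresholds delta_1..delta_m.
Thresholds are anchored inputs here, not estimated.  On a candidate's map,
each score category is placed at its own threshold difficulty: attained
categories (1..x for attained score x) on the left, unattained on the right —
the polytomous analogue of the dichotomous correct/incorrect split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DomainError, Side, ValidationError

__all__ = ["PcmItem", "PcmPlacement", "pcm_category_probability", "map_pcm_to_gim"]


@dataclass
class PcmItem:
    """A polytomous item with anchored adjacent-category thresholds (logits)."""

    item_id: str
    subject_cluster: str
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or len(self.thresholds) < 1:
            raise ValidationError("thresholds must be a non-empty vector")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValidationError("thresholds must be finite")

    @property
    def max_score(self) -> int:
        return len(self.thresholds)


@dataclass
class CategoryPlacement:
    category: int
    side: Side
    y: float


@dataclass
class PcmPlacement:
    """Per-category placement for one PCM item: attained categories left."""

    item_id: str
    attained_score: int
    categories: list[CategoryPlacement]

    @property
    def left(self) -> list[CategoryPlacement]:
        return [c for c in self.categories if c.side is Side.LEFT_CORRECT]

    @property
    def right(self) -> list[CategoryPlacement]:
        return [c for c in self.categories if c.side is Side.RIGHT_INCORRECT]


def pcm_category_probability(theta: float, thresholds) -> np.ndarray:
    """Probability vector over scores 0..m under the PCM.

    Computed in log space (log-sum-exp) so extreme thetas stay normalised.
    With a single threshold the PCM reduces exactly to the dichotomous Rasch
    item characteristic curve.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if not (np.isfinite(theta) and np.all(np.isfinite(thresholds))):
        raise DomainError("pcm_category_probability requires finite inputs")
    # cumulative log-numerators: 0 for k=0, sum_{j<=k}(theta - delta_j) after
    lognum = np.concatenate([[0.0], np.cumsum(theta - thresholds)])
    lognum -= lognum.max()
    p = np.exp(lognum)
    return p / p.sum()


def map_pcm_to_gim(attained_score: int, item: PcmItem) -> PcmPlacement:
    """Place each score category of a PCM item on the candidate's map.

    Categories 1..attained go left (attained) at their threshold difficulty;
    categories attained+1..m go right (not attained) at theirs.  A candidate
    scoring 2 of a possible 3 therefore sees categories 1 and 2 on the left
    and category 3 on the right.
    """
    m = item.max_score
    if not 0 <= attained_score <= m:
        raise DomainError(f"attained_score {attained_score} outside [0, {m}]")
    cats = []
    for k in range(1, m + 1):
        side = Side.LEFT_CORRECT if k <= attained_score else Side.RIGHT_INCORRECT
        cats.append(CategoryPlacement(category=k, side=side,
                                      y=float(item.thresholds[k - 1])))
    return PcmPlacement(item_id=item.item_id, attained_score=attained_score,
                        categories=cats)
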