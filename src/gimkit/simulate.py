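"""Seeded synthetic response generation under the Rasch and PCM models.

Provides the exam-shaped fixture used throughout the test suite: 60
dichotomous items over the eight canonical subject clusters, difficulties
spanning [-3, 3], and a cohort of candidates with normally distributed
abilities answering via the Rasch item characteristic curve.  Equal seeds
give equal outputs on one platform (numpy PCG64 generator).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import (
    CANONICAL_CLUSTERS,
    CalibrationConstraint,
    ItemBank,
    ItemRecord,
    ResponseMatrix,
    SimulationSpec,
    ValidationError,
)
from .pcm import pcm_category_probability
from .rasch import icc_probability

__all__ = ["simulate_rasch", "simulate_pcm", "make_fsep_fixture"]


def simulate_rasch(spec: SimulationSpec) -> tuple[ResponseMatrix, np.ndarray]:
    """Draw a dichotomous response matrix from the Rasch model.

    Abilities are Normal(ability_mean, ability_sd); each response is
    Bernoulli at the item characteristic curve.  Returns the matrix and the
    true abilities.
    """
    if spec.model != "rasch":
        raise ValidationError(f"spec.model is {spec.model!r}, expected 'rasch'")
    rng = np.random.default_rng(spec.seed)
    theta = rng.normal(spec.ability_mean, spec.ability_sd, size=spec.n_persons)
    P = icc_probability(theta[:, None], spec.difficulties[None, :])
    X = (rng.random(P.shape) < P).astype(int)
    resp = ResponseMatrix(
        candidate_ids=[f"C{i + 1:04d}" for i in range(spec.n_persons)],
        item_ids=[f"Q{j + 1:02d}" for j in range(len(spec.difficulties))],
        scores=X,
    )
    return resp, theta


def simulate_pcm(spec: SimulationSpec,
                 thresholds: Sequence[np.ndarray]) -> ResponseMatrix:
    """Draw polytomous scores from the Partial Credit Model.

    ``thresholds`` holds one adjacent-category threshold vector per item;
    each person/item score is drawn from the PCM category distribution at
    the person's ability.
    """
    if spec.model != "pcm":
        raise ValidationError(f"spec.model is {spec.model!r}, expected 'pcm'")
    rng = np.random.default_rng(spec.seed)
    theta = rng.normal(spec.ability_mean, spec.ability_sd, size=spec.n_persons)
    n_items = len(thresholds)
    scores = np.zeros((spec.n_persons, n_items), dtype=int)
    u = rng.random((spec.n_persons, n_items))
    for j, thr in enumerate(thresholds):
        for i, t in enumerate(theta):
            probs = pcm_category_probability(t, thr)
            scores[i, j] = int(np.searchsorted(np.cumsum(probs), u[i, j]))
    return ResponseMatrix(
        candidate_ids=[f"C{i + 1:04d}" for i in range(spec.n_persons)],
        item_ids=[f"P{j + 1:02d}" for j in range(n_items)],
        scores=scores,
        max_scores=np.array([len(t) for t in thresholds], dtype=int),
    )


def make_fsep_fixture(seed: int = 0, n_persons: int = 200,
                      n_items: int = 60) -> tuple[ItemBank, ResponseMatrix, np.ndarray]:
    """Exam-shaped synthetic fixture standing in for confidential data.

    60 dichotomous items with difficulties evenly spaced on [-3, 3]
    (re-centred to mean zero), subject clusters assigned round-robin over
    the eight canonical labels, and 200 candidates with abilities
    Normal(0.5, 1).  Returns (bank, responses, true_abilities).
    """
    deltas = np.linspace(-3.0, 3.0, n_items)
    deltas = deltas - deltas.mean()
    items = [
        ItemRecord(
            item_id=f"Q{j + 1:02d}",
            subject_cluster=CANONICAL_CLUSTERS[j % len(CANONICAL_CLUSTERS)],
            answer_key=1,
            difficulty=float(deltas[j]),
        )
        for j in range(n_items)
    ]
    bank = ItemBank(items=items, calibration_constraint=CalibrationConstraint.MEAN_ZERO)
    spec = SimulationSpec(n_persons=n_persons, difficulties=deltas,
                          ability_mean=0.5, ability_sd=1.0, seed=seed)
    responses, theta = simulate_rasch(spec)
    return bank, responses, theta
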