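"""Dichotomous Rasch model: CML item calibration, WLE ability, fit statistics.

The Rasch model puts persons (ability :math:`\\theta`) and items (difficulty
:math:`\\delta`) on one logit scale, with

.. math:: P(X_{ni}=1) = \\frac{e^{\\theta_n-\\delta_i}}{1+e^{\\theta_n-\\delta_i}}.

Item difficulties are estimated by conditional maximum likelihood (CML):
conditioning on each person's raw score eliminates the person parameters, so
no ability distribution is assumed.  The conditional likelihood is driven by
the elementary symmetric functions (ESF) :math:`\\gamma_r` of the item
easiness terms :math:`\\varepsilon_i = e^{-\\delta_i}`.  Person abilities are
measured by Warm's weighted likelihood estimator (WLE), which stays finite
at zero and perfect raw scores — every candidate gets a map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .model import DomainError, PersonEstimate, ResponseMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "icc_probability",
    "elementary_symmetric",
    "esf_without",
    "CalibrationResult",
    "CalibrationConfig",
    "calibrate_cml",
    "estimate_ability_wle",
    "estimate_persons",
    "expected_score",
    "invert_tcc",
    "FitStatistics",
    "item_fit",
]


def icc_probability(theta, delta):
    """Rasch item characteristic curve P(correct | theta, delta).

    Accepts scalars or broadcastable arrays; strictly in (0, 1), increasing
    in ``theta`` and decreasing in ``delta``.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(delta))):
        raise DomainError("icc_probability requires finite theta and delta")
    out = expit(theta - delta)
    if out.ndim == 0:
        return float(out)
    return out


def elementary_symmetric(deltas: Sequence[float]) -> np.ndarray:
    """ESF vector gamma_0..gamma_n of the easiness terms exp(-delta_i).

    gamma_r is the sum over all r-subsets S of prod_{i in S} exp(-delta_i),
    computed by the stable one-item-at-a-time summation recursion
    (never by subset enumeration):

        gamma^{(+item)}_r = gamma_r + eps_i * gamma_{r-1}.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 1:
        raise DomainError("deltas must be a 1-D vector")
    if not np.all(np.isfinite(deltas)):
        raise DomainError("deltas must be finite")
    eps = np.exp(-deltas)
    gamma = np.zeros(len(deltas) + 1)
    gamma[0] = 1.0
    for i, e in enumerate(eps):
        # in-place reverse update keeps gamma[: i + 2] current
        gamma[1 : i + 2] = gamma[1 : i + 2] + e * gamma[0 : i + 1]
    return gamma


def esf_without(gamma: np.ndarray, eps_j: float) -> np.ndarray:
    """Deflate one item out of an ESF vector: gamma of the remaining items.

    Forward deflation ``g_r = gamma_r - eps_j g_{r-1}`` is stable for small
    easiness; for ``eps_j > 1`` the backward recursion
    ``g_{r-1} = (gamma_r - g_r) / eps_j`` is used instead.  Accuracy degrades
    for long vectors with a wide easiness range; the calibration internals
    therefore use the cancellation-free split-and-merge construction below
    rather than this convenience.
    """
    n = len(gamma) - 1
    g = np.empty(n)
    if eps_j <= 1.0:
        acc = 1.0
        g[0] = 1.0
        for r in range(1, n):
            acc = gamma[r] - eps_j * acc
            g[r] = acc
    else:
        acc = gamma[n] / eps_j
        g[n - 1] = acc
        for r in range(n - 1, 0, -1):
            acc = (gamma[r] - acc) / eps_j
            g[r - 1] = acc
    return g


def _prefix_suffix_esf(eps: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Prefix and suffix ESF vectors: F[k] over eps[:k], B[k] over eps[k:]."""
    n = len(eps)
    F: list[np.ndarray] = [np.ones(1)]
    for k in range(n):
        prev = F[-1]
        nxt = np.zeros(len(prev) + 1)
        nxt[:-1] += prev
        nxt[1:] += eps[k] * prev
        F.append(nxt)
    B: list[np.ndarray] = [np.ones(1)] * (n + 1)
    B[n] = np.ones(1)
    for k in range(n - 1, -1, -1):
        prev = B[k + 1]
        nxt = np.zeros(len(prev) + 1)
        nxt[:-1] += prev
        nxt[1:] += eps[k] * prev
        B[k] = nxt
    return F, B


def _esf_leave_one_out(eps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full ESF vector and the matrix G1[i, r] = gamma_r of all items but i.

    Built by merging prefix and suffix ESFs (a positive-term convolution),
    which is cancellation-free and stable for any easiness range.
    """
    n = len(eps)
    F, B = _prefix_suffix_esf(eps)
    gamma = F[n]
    G1 = np.empty((n, n))
    for i in range(n):
        G1[i] = np.convolve(F[i], B[i + 1])
    return gamma, G1


def _conditional_information(deltas: np.ndarray,
                             score_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Conditional expectations pi[i, r-1] = E[x_i | r] and the information
    matrix H = sum_r n_r Cov(x | r) of the conditional likelihood."""
    n = len(deltas)
    eps = np.exp(-deltas)
    gamma, G1 = _esf_leave_one_out(eps)
    rs = np.arange(1, n + 1)
    pi = eps[:, None] * G1[:, rs - 1] / gamma[rs][None, :]
    w = score_counts[rs]
    H = np.zeros((n, n))
    for i in range(n):
        reduced = np.delete(eps, i)
        Fr, Br = _prefix_suffix_esf(reduced)
        for k in range(i, n - 1):  # reduced index k maps to original j = k + 1 > i
            j = k + 1
            g_ij = np.convolve(Fr[k], Br[k + 1])  # ESF without items i and j
            # E[x_i x_j | r] = eps_i eps_j gamma^{(ij)}_{r-2} / gamma_r
            e2 = np.zeros(n)
            e2[1:] = eps[i] * eps[j] * g_ij[: n - 1] / gamma[rs[1:]]
            H[i, j] = H[j, i] = np.dot(w, e2 - pi[i] * pi[j])
        H[i, i] = np.dot(w, pi[i] * (1 - pi[i]))
    return pi, H


@dataclass
class CalibrationConfig:
    """Settings for CML calibration."""

    gradient_tol: float = 1e-8
    max_iterations: int = 100
    mean_zero: bool = True


@dataclass
class CalibrationResult:
    item_ids: list[str]
    difficulties: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    iterations: int
    excluded_items: list[str] = field(default_factory=list)
    excluded_persons: list[str] = field(default_factory=list)

    def difficulty_of(self, item_id: str) -> float:
        return float(self.difficulties[self.item_ids.index(item_id)])


def _conditional_neg_loglik(deltas: np.ndarray, item_totals: np.ndarray,
                            score_counts: np.ndarray) -> float:
    """Negative conditional log-likelihood given raw-score counts.

    ell = -sum_i s_i delta_i - sum_r n_r log gamma_r, with s_i the item
    totals over retained persons and n_r the raw-score frequencies.
    """
    gamma = elementary_symmetric(deltas)
    r = np.arange(len(gamma))
    return float(np.dot(item_totals, deltas) + np.dot(score_counts, np.log(gamma)))


def calibrate_cml(responses: ResponseMatrix,
                  config: Optional[CalibrationConfig] = None) -> CalibrationResult:
    """CML item calibration by Newton iteration on the conditional likelihood.

    Persons with zero or perfect raw scores carry no conditional information
    and are excluded (reported in ``excluded_persons``); items answered
    all-correct or all-incorrect by the retained persons have no finite CML
    estimate and are excluded (reported in ``excluded_items``).  Iterates
    Newton steps with the exact conditional information matrix until
    ``max |gradient| < gradient_tol`` (default 1e-8) or ``max_iterations``.
    Under the mean-zero constraint the reported difficulties average to 0.
    """
    config = config or CalibrationConfig()
    X = responses.scores.astype(float)
    item_ids = list(responses.item_ids)
    cand_ids = list(responses.candidate_ids)
    if X.shape[1] < 2:
        raise ValidationError("calibration requires at least 2 items")

    excluded_items: list[str] = []
    excluded_persons: list[str] = []
    keep_items = np.ones(X.shape[1], dtype=bool)
    keep_persons = np.ones(X.shape[0], dtype=bool)
    # alternate exclusion until stable: dropping persons can degenerate items
    # and vice versa
    while True:
        sub = X[np.ix_(keep_persons, keep_items)]
        n_it = sub.shape[1]
        raw = sub.sum(axis=1)
        bad_p = (raw == 0) | (raw == n_it)
        tot = sub.sum(axis=0)
        n_p = sub.shape[0]
        bad_i = (tot == 0) | (tot == n_p)
        if not bad_p.any() and not bad_i.any():
            break
        if bad_p.any():
            idx = np.flatnonzero(keep_persons)[bad_p]
            excluded_persons.extend(cand_ids[i] for i in idx)
            keep_persons[idx] = False
        sub = X[np.ix_(keep_persons, keep_items)]
        if sub.shape[0] == 0:
            break
        tot = sub.sum(axis=0)
        bad_i = (tot == 0) | (tot == sub.shape[0])
        if bad_i.any():
            idx = np.flatnonzero(keep_items)[bad_i]
            excluded_items.extend(item_ids[i] for i in idx)
            keep_items[idx] = False
        if keep_items.sum() < 2:
            break

    kept_ids = [iid for iid, k in zip(item_ids, keep_items) if k]
    sub = X[np.ix_(keep_persons, keep_items)]
    n = sub.shape[1]
    if n < 2 or sub.shape[0] == 0:
        raise ValidationError(
            "calibration impossible: fewer than 2 non-degenerate items remain"
        )

    item_totals = sub.sum(axis=0)
    raw = sub.sum(axis=1).astype(int)
    score_counts = np.bincount(raw, minlength=n + 1).astype(float)

    # PROX-style start: logit of item facility, centred
    p = item_totals / sub.shape[0]
    deltas = -np.log(p / (1 - p))
    deltas -= deltas.mean()

    converged = False
    it = 0
    w = score_counts[np.arange(1, n + 1)]
    for it in range(1, config.max_iterations + 1):
        # pi[i, r-1] = E[x_i | raw score r]; H = conditional information
        pi, H = _conditional_information(deltas, score_counts)
        grad = item_totals - pi @ w
        if np.max(np.abs(grad)) < config.gradient_tol:
            converged = True
            break
        # H is singular along the all-ones gauge direction; pin it
        Haug = H + np.ones((n, n)) / n
        try:
            step = -np.linalg.solve(Haug, grad)
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(H, grad, rcond=None)[0]
        step -= step.mean()
        if np.max(np.abs(grad)) < 1e-4:
            # near the optimum the objective's float precision cannot verify
            # descent; plain Newton is quadratically convergent here
            deltas = deltas + step
            deltas -= deltas.mean()
            continue
        # damped line search on the conditional likelihood
        f0 = _conditional_neg_loglik(deltas, item_totals, score_counts)
        lam = 1.0
        for _ in range(30):
            trial = deltas + lam * step
            trial -= trial.mean()
            if _conditional_neg_loglik(trial, item_totals, score_counts) < f0 + 1e-10 * max(1.0, abs(f0)):
                deltas = trial
                break
            lam *= 0.5
        else:
            break

    if config.mean_zero:
        deltas = deltas - deltas.mean()

    # SEs from the inverse conditional information on the mean-zero subspace
    _, H = _conditional_information(deltas, score_counts)
    Haug = H + np.ones((n, n)) / n
    try:
        cov = np.linalg.inv(Haug)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    ses[ses == 0] = np.nan

    if not converged:
        logger.warning("CML calibration did not converge in %d iterations", it)

    return CalibrationResult(
        item_ids=kept_ids,
        difficulties=deltas,
        standard_errors=ses,
        converged=converged,
        iterations=it,
        excluded_items=excluded_items,
        excluded_persons=excluded_persons,
    )


def _wle_score(theta: float, deltas: np.ndarray, r: int) -> float:
    p = expit(theta - deltas)
    info = np.sum(p * (1 - p))
    j = np.sum(p * (1 - p) * (1 - 2 * p))
    return r - float(np.sum(p)) + float(j) / (2.0 * float(info))


def estimate_ability_wle(raw_score: int, deltas: Sequence[float],
                         candidate_id: str = "", tol: float = 1e-10) -> PersonEstimate:
    """Warm's weighted likelihood ability estimate for one raw score.

    Solves ``r - sum_i p_i + J/(2I) = 0`` (p_i the ICC at theta, I the test
    information, J its bias-correction numerator) by safeguarded
    Newton/bisection to ``|residual| < tol``.  Finite for r = 0 and r = n,
    unlike plain ML.  SE is ``1/sqrt(I)`` at the estimate.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    if not (0 <= raw_score <= n):
        raise DomainError(f"raw_score {raw_score} outside [0, {n}]")
    if n == 0:
        raise DomainError("cannot estimate ability with zero items")

    # bracket a sign change; the WLE score is strictly decreasing in theta
    lo, hi = float(deltas.min()) - 5.0, float(deltas.max()) + 5.0
    while _wle_score(lo, deltas, raw_score) < 0:
        lo -= 5.0
    while _wle_score(hi, deltas, raw_score) > 0:
        hi += 5.0
    theta = 0.5 * (lo + hi)
    for _ in range(200):
        f = _wle_score(theta, deltas, raw_score)
        if abs(f) < tol:
            break
        if f > 0:
            lo = theta
        else:
            hi = theta
        p = expit(theta - deltas)
        info = float(np.sum(p * (1 - p)))
        step = f / info  # Newton on the dominant -I slope
        candidate = theta + step
        if not (lo < candidate < hi):
            candidate = 0.5 * (lo + hi)
        theta = candidate
    p = expit(theta - deltas)
    info = float(np.sum(p * (1 - p)))
    return PersonEstimate(
        candidate_id=candidate_id,
        raw_score=int(raw_score),
        ability=float(theta),
        standard_error=1.0 / math.sqrt(info),
        n_administered=n,
    )


def estimate_persons(responses: ResponseMatrix,
                     deltas: Sequence[float]) -> list[PersonEstimate]:
    """WLE estimates for every candidate; equal raw scores share one solve."""
    deltas = np.asarray(deltas, dtype=float)
    cache: dict[int, PersonEstimate] = {}
    out = []
    for cid, r in zip(responses.candidate_ids, responses.raw_scores()):
        r = int(r)
        if r not in cache:
            cache[r] = estimate_ability_wle(r, deltas)
        base = cache[r]
        out.append(PersonEstimate(cid, base.raw_score, base.ability,
                                  base.standard_error, base.n_administered))
    return out


def expected_score(theta: float, deltas: Sequence[float]) -> float:
    """Test characteristic curve: expected raw score sum_i P(theta, delta_i)."""
    deltas = np.asarray(deltas, dtype=float)
    if not (np.isfinite(theta) and np.all(np.isfinite(deltas))):
        raise DomainError("expected_score requires finite inputs")
    return float(np.sum(expit(theta - deltas)))


def invert_tcc(target_score: float, deltas: Sequence[float],
               tol: float = 1e-8) -> float:
    """Ability at which the TCC equals ``target_score`` (bisection).

    Converts a raw or percentage pass mark into the logit pass line.  The
    target must lie strictly inside (0, n): the TCC reaches its bounds only
    in the limit, so no finite solution exists at 0 or n.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    if not 0 < target_score < n:
        raise DomainError(f"target_score must lie strictly in (0, {n})")
    lo, hi = float(deltas.min()) - 5.0, float(deltas.max()) + 5.0
    while expected_score(lo, deltas) > target_score:
        lo -= 5.0
    while expected_score(hi, deltas) < target_score:
        hi += 5.0
    while hi - lo > 1e-14:
        mid = 0.5 * (lo + hi)
        val = expected_score(mid, deltas)
        if abs(val - target_score) < tol:
            return mid
        if val < target_score:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class FitStatistics:
    """Infit/outfit mean-square residual statistics for one item."""

    item_id: str
    infit_ms: float
    outfit_ms: float


def item_fit(responses: ResponseMatrix, deltas: Sequence[float],
             abilities: Sequence[PersonEstimate],
             eps: float = 1e-12) -> list[FitStatistics]:
    """Residual-based item fit: outfit (unweighted) and infit (information-
    weighted) mean squares.

    With standardised residuals z_ni = (x_ni - p_ni)/sqrt(p_ni(1-p_ni)):
    outfit_ms(i) = mean_n z_ni^2 and
    infit_ms(i) = sum_n (x_ni - p_ni)^2 / sum_n p_ni(1-p_ni).
    Cells with p numerically 0 or 1 are excluded (count logged).
    Under the model both statistics have expectation 1; a miskeyed or
    malfunctioning item inflates them.
    """
    deltas = np.asarray(deltas, dtype=float)
    theta = np.array([a.ability for a in abilities], dtype=float)
    X = responses.scores.astype(float)
    P = expit(theta[:, None] - deltas[None, :])
    ok = (P > eps) & (P < 1 - eps)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("item_fit: excluded %d cells with degenerate p", n_dropped)
    resid2 = np.where(ok, (X - P) ** 2, 0.0)
    var = np.where(ok, P * (1 - P), 0.0)
    counts = ok.sum(axis=0)
    out = []
    for i, iid in enumerate(responses.item_ids):
        if counts[i] == 0:
            out.append(FitStatistics(iid, float("nan"), float("nan")))
            continue
        outfit = float(np.sum(np.where(ok[:, i], resid2[:, i] / np.where(ok[:, i], var[:, i], 1.0), 0.0)) / counts[i])
        infit = float(resid2[:, i].sum() / var[:, i].sum())
        out.append(FitStatistics(iid, infit, outfit))
    return out
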