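"""Rasch engine: ICC, elementary symmetric functions, CML, WLE, TCC, fit."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from gimkit import (
    calibrate_cml,
    elementary_symmetric,
    estimate_ability_wle,
    estimate_persons,
    expected_score,
    icc_probability,
    invert_tcc,
    item_fit,
    make_fsep_fixture,
)
from gimkit.model import DomainError, ResponseMatrix, SimulationSpec
from gimkit.rasch import _conditional_neg_loglik, esf_without
from gimkit.simulate import simulate_rasch

# ---------------------------------------------------------------------------
# oracles


def esf_by_enumeration(deltas):
    """Brute-force ESF oracle: explicit sum over all subsets."""
    eps = np.exp(-np.asarray(deltas, dtype=float))
    n = len(eps)
    gamma = np.zeros(n + 1)
    for r in range(n + 1):
        gamma[r] = sum(
            np.prod([eps[i] for i in S]) for S in itertools.combinations(range(n), r)
        )
    return gamma


def wle_by_grid(raw_score, deltas, lo=-8.0, hi=8.0):
    """Grid-search maximiser of the weighted likelihood (two-stage grid)."""
    deltas = np.asarray(deltas, dtype=float)

    def wloglik(theta):
        p = expit(np.subtract.outer(np.atleast_1d(theta), deltas))
        info = np.sum(p * (1 - p), axis=1)
        ll = raw_score * np.atleast_1d(theta) - np.sum(
            np.log1p(np.exp(np.subtract.outer(np.atleast_1d(theta), deltas))), axis=1
        )
        return ll + 0.5 * np.log(info)

    grid = np.arange(lo, hi, 1e-3)
    best = grid[np.argmax(wloglik(grid))]
    fine = np.arange(best - 2e-3, best + 2e-3, 1e-7)
    return fine[np.argmax(wloglik(fine))]


# ---------------------------------------------------------------------------
# ICC


class TestIcc:
    @pytest.mark.parametrize(
        "theta,delta,expected",
        [(0.0, 0.0, 0.5), (math.log(3), 0.0, 0.75), (0.0, math.log(3), 0.25)],
    )
    def test_closed_form_values(self, theta, delta, expected):
        assert icc_probability(theta, delta) == pytest.approx(expected, abs=1e-12)

    @given(
        theta=st.floats(-10, 10),
        delta=st.floats(-10, 10),
        c=st.floats(-5, 5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_translation_gauge(self, theta, delta, c):
        """Shifting both ability and difficulty leaves the probability fixed."""
        p0 = icc_probability(theta, delta)
        p1 = icc_probability(theta + c, delta + c)
        assert p1 == pytest.approx(p0, abs=1e-12)
        assert 0.0 < p0 < 1.0

    def test_monotone_in_theta_and_delta(self):
        thetas = np.linspace(-4, 4, 50)
        p = icc_probability(thetas, 0.3)
        assert np.all(np.diff(p) > 0)
        p2 = icc_probability(0.3, thetas)
        assert np.all(np.diff(p2) < 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            icc_probability(np.nan, 0.0)


# ---------------------------------------------------------------------------
# elementary symmetric functions


class TestEsf:
    def test_equal_items_give_binomial_coefficients(self):
        assert np.allclose(elementary_symmetric([0.0, 0.0, 0.0]), [1, 3, 3, 1])

    def test_empty_vector(self):
        assert np.allclose(elementary_symmetric([]), [1.0])

    def test_matches_enumeration_oracle(self):
        deltas = np.array([-1.0, 0.0, 2.0])
        gamma = elementary_symmetric(deltas)
        oracle = esf_by_enumeration(deltas)
        assert np.allclose(gamma, oracle, rtol=1e-12)

    def test_random_vectors_match_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(1, 13)
            deltas = rng.normal(0, 1.5, n)
            gamma = elementary_symmetric(deltas)
            oracle = esf_by_enumeration(deltas)
            assert np.allclose(gamma, oracle, rtol=1e-10)
            assert gamma[0] == 1.0 and np.all(gamma > 0)

    def test_deflation_inverts_extension(self):
        rng = np.random.default_rng(4)
        deltas = rng.normal(0, 1.0, 8)
        gamma = elementary_symmetric(deltas)
        for j in range(8):
            reduced = esf_without(gamma, math.exp(-deltas[j]))
            direct = elementary_symmetric(np.delete(deltas, j))
            assert np.allclose(reduced, direct, rtol=1e-9)


# ---------------------------------------------------------------------------
# CML calibration


def cml_oracle(responses, n_items, start=None):
    """Derivative-free maximisation of the same conditional likelihood."""
    X = responses.scores.astype(float)
    raw = X.sum(axis=1)
    keep = (raw > 0) & (raw < n_items)
    sub = X[keep]
    item_totals = sub.sum(axis=0)
    score_counts = np.bincount(sub.sum(axis=1).astype(int), minlength=n_items + 1).astype(float)

    def objective(free):
        d = np.concatenate([free, [-free.sum()]])
        return _conditional_neg_loglik(d, item_totals, score_counts)

    x0 = np.zeros(n_items - 1) if start is None else start
    res = minimize(objective, x0, method="Powell",
                   options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 100000})
    res = minimize(objective, res.x, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-15,
                            "maxiter": 100000, "maxfev": 100000})
    return np.concatenate([res.x, [-res.x.sum()]])


class TestCalibrateCml:
    def test_matches_derivative_free_oracle(self):
        _, resp, _ = make_fsep_fixture(seed=1, n_persons=200, n_items=5)
        result = calibrate_cml(resp)
        assert result.converged
        oracle = cml_oracle(resp, 5)
        assert np.max(np.abs(result.difficulties - oracle)) < 1e-6

    def test_mean_zero_constraint_and_positive_ses(self):
        _, resp, _ = make_fsep_fixture(seed=9, n_persons=300, n_items=10)
        result = calibrate_cml(resp)
        assert abs(result.difficulties.mean()) < 1e-8
        assert np.all(result.standard_errors > 0)

    def test_symmetric_two_item_pattern(self):
        """Swapping the two items' response patterns forces delta = (-d, +d)."""
        # counts chosen symmetric under item swap among score-1 persons
        rows = [[1, 0]] * 30 + [[0, 1]] * 30 + [[1, 1]] * 20 + [[0, 0]] * 20
        resp = ResponseMatrix(
            candidate_ids=[f"P{i}" for i in range(100)],
            item_ids=["A", "B"],
            scores=np.array(rows),
        )
        result = calibrate_cml(resp)
        assert result.difficulties[0] == pytest.approx(-result.difficulties[1], abs=1e-10)

    def test_column_permutation_equivariance(self):
        _, resp, _ = make_fsep_fixture(seed=5, n_persons=250, n_items=6)
        result = calibrate_cml(resp)
        perm = [3, 1, 5, 0, 2, 4]
        shuffled = ResponseMatrix(
            candidate_ids=list(resp.candidate_ids),
            item_ids=[resp.item_ids[j] for j in perm],
            scores=resp.scores[:, perm],
        )
        result2 = calibrate_cml(shuffled)
        lookup = dict(zip(result2.item_ids, result2.difficulties))
        for iid, d in zip(result.item_ids, result.difficulties):
            assert lookup[iid] == pytest.approx(d, abs=1e-9)

    def test_extreme_persons_and_degenerate_items_reported(self):
        scores = np.array([
            [1, 1, 1],  # perfect -> excluded person
            [0, 0, 0],  # zero -> excluded person
            [1, 0, 1],
            [0, 1, 1],
            [1, 1, 1],  # perfect
            [1, 0, 1],
            [0, 0, 1],
            [1, 1, 1],  # perfect
        ])
        resp = ResponseMatrix(
            candidate_ids=[f"P{i}" for i in range(8)],
            item_ids=["A", "B", "C"],
            scores=scores,
        )
        result = calibrate_cml(resp)
        # P6 cascades: once degenerate item C drops, its raw score becomes 0
        assert set(result.excluded_persons) == {"P0", "P1", "P4", "P6", "P7"}
        # item C is correct for every retained person -> degenerate
        assert result.excluded_items == ["C"]
        assert result.item_ids == ["A", "B"]

    def test_parameter_recovery(self):
        """Simulated 60-item exams recover the generating difficulties."""
        for seed in (1, 2, 3):
            bank, resp, _ = make_fsep_fixture(seed=seed, n_persons=2000)
            result = calibrate_cml(resp)
            true = bank.difficulties()
            idx = [bank.item_ids.index(i) for i in result.item_ids]
            corr = np.corrcoef(result.difficulties, true[idx])[0, 1]
            rmse = float(np.sqrt(np.mean((result.difficulties - true[idx]) ** 2)))
            assert corr >= 0.98
            assert rmse <= 0.15


# ---------------------------------------------------------------------------
# WLE ability


class TestWle:
    def test_symmetric_bank_half_score_gives_zero(self):
        est = estimate_ability_wle(2, [-1.0, -1.0, 1.0, 1.0])
        assert est.ability == pytest.approx(0.0, abs=1e-9)

    def test_depends_on_raw_score_only(self):
        deltas = [-1.0, 0.0, 2.0]
        a = estimate_ability_wle(2, deltas)
        b = estimate_ability_wle(2, deltas)
        assert a.ability == b.ability and a.standard_error == b.standard_error

    def test_matches_grid_oracle(self):
        deltas = [-1.0, 0.0, 2.0]
        for r in range(0, 4):
            est = estimate_ability_wle(r, deltas)
            oracle = wle_by_grid(r, deltas)
            assert est.ability == pytest.approx(oracle, abs=1e-6)

    def test_finite_at_extreme_scores(self):
        deltas = np.linspace(-3, 3, 60)
        for r in (0, 60):
            est = estimate_ability_wle(r, deltas)
            assert math.isfinite(est.ability)
            assert est.standard_error > 0

    def test_out_of_range_raw_score(self):
        with pytest.raises(DomainError):
            estimate_ability_wle(4, [-1.0, 0.0, 1.0])

    def test_sufficiency_bitwise_equality(self, fsep):
        """Equal raw scores on the same item set give bitwise-equal estimates."""
        bank, resp, _ = fsep
        estimates = estimate_persons(resp, bank.difficulties())
        by_score = {}
        for e in estimates:
            by_score.setdefault(e.raw_score, []).append(e)
        for group in by_score.values():
            assert len({e.ability for e in group}) == 1
            assert len({e.standard_error for e in group}) == 1

    def test_monotone_in_raw_score(self):
        deltas = np.linspace(-2, 2, 20)
        abilities = [estimate_ability_wle(r, deltas).ability for r in range(21)]
        assert np.all(np.diff(abilities) > 0)


# ---------------------------------------------------------------------------
# TCC and inversion


class TestTcc:
    def test_all_zero_bank_midpoint(self):
        assert expected_score(0.0, np.zeros(60)) == pytest.approx(30.0, abs=1e-12)

    def test_closed_form_sum(self):
        deltas = np.array([-1.0, 0.0, 2.0])
        direct = sum(1 / (1 + math.exp(-(1.0 - d))) for d in deltas)
        assert expected_score(1.0, deltas) == pytest.approx(direct, abs=1e-12)

    def test_strictly_monotone_and_limits(self):
        deltas = np.linspace(-3, 3, 60)
        thetas = np.linspace(-6, 6, 200)
        vals = [expected_score(t, deltas) for t in thetas]
        assert np.all(np.diff(vals) > 0)
        assert expected_score(30.0, deltas) > 59.99

    def test_inversion_round_trip(self, fsep):
        bank, _, _ = fsep
        deltas = bank.difficulties()
        for theta in (-2.0, -1.0, 0.0, 1.0, 2.0):
            back = invert_tcc(expected_score(theta, deltas), deltas)
            assert abs(back - theta) < 1e-8

    def test_pass_mark_matches_grid_search(self, fsep):
        bank, _, _ = fsep
        deltas = bank.difficulties()
        target = 45.0  # 75% of 60
        theta = invert_tcc(target, deltas)
        # oracle: two-stage dense grid search for the TCC crossing
        grid = np.arange(-6, 6, 1e-3)
        vals = np.sum(expit(np.subtract.outer(grid, deltas)), axis=1)
        coarse = grid[np.argmin(np.abs(vals - target))]
        fine = np.arange(coarse - 2e-3, coarse + 2e-3, 1e-7)
        vals = np.sum(expit(np.subtract.outer(fine, deltas)), axis=1)
        oracle = fine[np.argmin(np.abs(vals - target))]
        assert theta == pytest.approx(oracle, abs=1e-5)

    def test_targets_outside_open_interval_rejected(self):
        deltas = np.zeros(10)
        for bad in (0.0, 10.0, -1.0, 11.0):
            with pytest.raises(DomainError):
                invert_tcc(bad, deltas)


# ---------------------------------------------------------------------------
# item fit


class TestItemFit:
    def test_hand_computed_tiny_matrix(self):
        """Direct evaluation of both mean-square formulas on fixed theta/delta."""
        deltas = np.array([-0.5, 0.5])
        thetas = np.array([-1.0, 0.0, 1.0])
        X = np.array([[1, 0], [0, 1], [1, 1]])
        resp = ResponseMatrix(
            candidate_ids=["a", "b", "c"], item_ids=["A", "B"], scores=X
        )
        from gimkit.model import PersonEstimate

        abilities = [
            PersonEstimate(c, int(X[i].sum()), float(thetas[i]), 1.0, 2)
            for i, c in enumerate(["a", "b", "c"])
        ]
        P = expit(thetas[:, None] - deltas[None, :])
        expected = []
        for j in range(2):
            z2 = (X[:, j] - P[:, j]) ** 2 / (P[:, j] * (1 - P[:, j]))
            outfit = z2.mean()
            infit = ((X[:, j] - P[:, j]) ** 2).sum() / (P[:, j] * (1 - P[:, j])).sum()
            expected.append((infit, outfit))
        fits = item_fit(resp, deltas, abilities)
        for f, (infit, outfit) in zip(fits, expected):
            assert f.infit_ms == pytest.approx(infit, rel=1e-12)
            assert f.outfit_ms == pytest.approx(outfit, rel=1e-12)

    def test_model_conforming_data_near_unity(self, calibrated_cohort):
        bank, resp, _, result = calibrated_cohort
        abilities = estimate_persons(resp, result.difficulties)
        fits = item_fit(resp, result.difficulties, abilities)
        in_band = [f for f in fits if 0.8 <= f.infit_ms <= 1.2 and 0.8 <= f.outfit_ms <= 1.2]
        assert len(in_band) >= 0.95 * len(fits)

    def test_miskeyed_item_inflates_outfit(self, calibrated_cohort):
        bank, resp, _, result = calibrated_cohort
        flipped = resp.scores.copy()
        flipped[:, 0] = 1 - flipped[:, 0]  # miskey item 0
        bad = ResponseMatrix(
            candidate_ids=list(resp.candidate_ids),
            item_ids=list(resp.item_ids),
            scores=flipped,
        )
        abilities = estimate_persons(bad, result.difficulties)
        fits = item_fit(bad, result.difficulties, abilities)
        assert fits[0].outfit_ms > 1.5
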