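"""The covariance-weighted Mahalanobis metric and its diagnostics."""

import numpy as np
import pandas as pd
import pytest

from cgam.core import (
    CGAM,
    cgam_score,
    compare_conditions,
    effective_weights,
    estimate_covariance,
    make_covariance_model,
)
from cgam.errors import InsufficientDataError, ParameterError
from cgam.simulate import generate_asymmetry_matrix


def _spd(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, n))
    return a @ a.T + n * np.eye(n)


class TestEstimateCovariance:
    def test_constructed_uncorrelated_columns(self):
        # sample variance exactly 1 and 4, zero cross-covariance
        c = np.sqrt(3.0) / 2.0
        X = np.column_stack([c * np.array([1, -1, 1, -1]),
                             2 * c * np.array([1, 1, -1, -1])])
        cov = estimate_covariance(X)
        np.testing.assert_allclose(cov.Sigma, np.diag([1.0, 4.0]), atol=1e-12)
        assert cov.S == pytest.approx(1.25, abs=1e-12)
        assert cov.ridge == 0.0

    def test_constant_column_triggers_ridge(self, caplog):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(size=30), np.full(30, 5.0)])
        with caplog.at_level("WARNING", logger="cgam.core"):
            cov = estimate_covariance(X)
        assert cov.ridge > 0
        assert "ridge" in caplog.text
        # inversion succeeded
        assert np.isfinite(cov.Sigma_inv).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_identity(self, seed):
        X = np.random.default_rng(seed).multivariate_normal(
            np.zeros(5), _spd(5, seed), size=60)
        cov = estimate_covariance(X)
        eye = cov.Sigma_inv @ (cov.Sigma + cov.ridge * np.eye(5))
        np.testing.assert_allclose(eye, np.eye(5), atol=1e-8)

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_covariance(np.ones((1, 3)))


class TestScore:
    def test_zero_matrix_scores_zero(self):
        res = cgam_score(np.zeros((10, 4)))
        assert res.score == pytest.approx(0.0, abs=1e-6)

    def test_diagonal_closed_form(self):
        res = cgam_score(np.array([[1.0, 2.0]]), cov=np.diag([1.0, 4.0]))
        assert res.per_step_sq[0] == pytest.approx(2.0, abs=1e-12)
        assert res.cov.S == pytest.approx(1.25, abs=1e-12)
        assert res.score == pytest.approx(np.sqrt(1.6), abs=1e-12)

    def test_matches_linear_solve_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(200, 11))
        res = cgam_score(X)
        Sigma = np.cov(X, rowvar=False, ddof=1) + res.cov.ridge * np.eye(11)
        q = np.array([row @ np.linalg.solve(Sigma, row) for row in X])
        S = np.ones(11) @ np.linalg.solve(Sigma, np.ones(11))
        want = np.mean(np.sqrt(q / S))
        assert abs(res.score - want) / want < 1e-10

    def test_gaussian_quadratic_form_expectation(self):
        # with a SUPPLIED covariance, E[q] = n + mu' Sigma^-1 mu
        n, m = 4, 4000
        Sigma = _spd(n, 3)
        mu = np.array([1.0, -0.5, 0.2, 0.8])
        mat, _ = generate_asymmetry_matrix(mu, Sigma, m, seed=5)
        res = cgam_score(mat.values, cov=Sigma)
        want = n + mu @ np.linalg.solve(Sigma, mu)
        se = res.per_step_sq.std(ddof=1) / np.sqrt(m)
        assert abs(res.per_step_sq.mean() - want) < 3 * se

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        perm = rng.permutation(6)
        np.testing.assert_allclose(cgam_score(X).score,
                                   cgam_score(X[:, perm]).score, rtol=1e-12)

    def test_distance_is_from_origin_not_mean(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        shifted = X.copy()
        shifted[:, 0] += 5.0  # mean shift leaves the covariance unchanged
        assert cgam_score(shifted).score > cgam_score(X).score

    def test_affine_invariance_of_quadratic_form(self):
        """With the covariance estimated from the data, per-step squared forms
        are invariant under any invertible linear map of the rows, while the
        normalizer S (hence the score) changes."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 5))
        A = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        res0 = cgam_score(X, ridge_policy="none")
        res1 = cgam_score(X @ A.T, ridge_policy="none")
        np.testing.assert_allclose(res0.per_step_sq, res1.per_step_sq, atol=1e-8)
        assert abs(res0.cov.S - res1.cov.S) > 1e-6

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ParameterError, match="covariance"):
            CGAM(np.ones((5, 3)), cov=np.eye(4))

    def test_monotone_in_injected_mean_scale(self):
        Sigma = _spd(5, 9)
        mu = np.ones(5) / np.sqrt(np.ones(5) @ np.linalg.solve(Sigma, np.ones(5)))
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.multivariate_normal(np.zeros(5), Sigma, size=200)
            scores = [cgam_score(s * mu + noise, cov=Sigma).score
                      for s in (0.0, 2.0, 4.0, 8.0, 16.0)]
            assert np.all(np.diff(scores) > 0)


class TestWeights:
    def test_identity_covariance_equal_weights(self):
        cov = make_covariance_model(np.eye(2))
        np.testing.assert_allclose(effective_weights(cov), [0.5, 0.5])

    def test_diagonal_hand_value(self):
        cov = make_covariance_model(np.diag([1.0, 4.0]))
        np.testing.assert_allclose(effective_weights(cov), [0.8, 0.2], atol=1e-12)

    def test_weight_decreases_with_variance(self):
        grid = np.linspace(0.5, 8.0, 10)
        w = [effective_weights(make_covariance_model(np.diag([v, 1.0, 2.0])))[0]
             for v in grid]
        assert np.all(np.diff(w) < 0)

    def test_weights_sum_to_one(self):
        for seed in range(5):
            cov = make_covariance_model(_spd(7, seed))
            assert effective_weights(cov).sum() == pytest.approx(1.0, abs=1e-12)


class TestCompare:
    def test_injected_asymmetry_ranks_higher(self):
        Sigma = 9 * np.eye(3)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base, _ = generate_asymmetry_matrix(np.zeros(3), Sigma, 50, seed=rng)
            pert, _ = generate_asymmetry_matrix(np.full(3, 10.0), Sigma, 50, seed=rng)
            df = compare_conditions([cgam_score(base.values),
                                     cgam_score(pert.values)],
                                    ["base", "pert"], seed=seed)
            wins += df["label"].iloc[0] == "pert"
        assert wins >= 19

    def test_nested_asymmetries_rank_in_order(self):
        Sigma = 4 * np.eye(3)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mats = [generate_asymmetry_matrix(np.full(3, a), Sigma, 100,
                                              seed=rng)[0]
                    for a in (0.0, 6.0, 12.0)]
            df = compare_conditions([cgam_score(m.values) for m in mats],
                                    ["none", "mid", "big"], seed=seed)
            assert list(df["label"]) == ["big", "mid", "none"]

    def test_identical_inputs_tie_keeps_order(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        df = compare_conditions([cgam_score(X), cgam_score(X)], ["a", "b"])
        assert list(df["label"]) == ["a", "b"]
        assert df["score"].iloc[0] == df["score"].iloc[1]

    def test_single_condition_rejected(self):
        with pytest.raises(ParameterError):
            compare_conditions([cgam_score(np.random.default_rng(0)
                                           .normal(size=(10, 2)))], ["only"])


class TestResultsObject:
    def test_summary_and_dict_roundtrip(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        res = CGAM.from_dataframe(pd.DataFrame(X, columns=["SL", "ST", "GRF"])).fit()
        text = res.summary()
        assert "SL" in text and "score" in text
        d = res.to_dict()
        assert d["score"] == pytest.approx(res.score)
        assert list(d["weights"]) == ["SL", "ST", "GRF"]

    def test_bootstrap_ci_brackets_score_and_is_seeded(self):
        X = np.random.default_rng(1).normal(size=(60, 3))
        res = cgam_score(X)
        lo, hi = res.conf_int(seed=42)
        assert lo < res.score < hi
        assert (lo, hi) == res.conf_int(seed=42)

    def test_aggregations(self):
        X = np.random.default_rng(2).normal(size=(40, 3))
        res = cgam_score(X)
        d = res.per_step_distance
        assert res.aggregate("median") == pytest.approx(np.median(d))
        assert res.aggregate("rms") >= res.aggregate("mean")
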