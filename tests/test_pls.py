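"""NIPALS core: standardization, extraction, deflation, fitting, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firefit import (
    ExtractionError,
    LoadedPLSResults,
    PLSRegression,
    deflate,
    extract_component,
    fit_plsr,
    standardize,
)


def _random_blocks(seed, n=12, m=4, p=3):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, m)), rng.standard_normal((n, p))


class TestStandardize:
    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((30, 4))
        Z1, _, _ = standardize(M)
        Z2, means, scales = standardize(Z1)
        np.testing.assert_allclose(Z2, Z1, atol=1e-12)
        np.testing.assert_allclose(means, 0, atol=1e-12)
        np.testing.assert_allclose(scales, 1, atol=1e-12)

    def test_constant_column_rejected_by_name(self):
        M = np.ones((5, 3))
        M[:, 0] = np.arange(5)
        M[:, 2] = np.arange(5)
        with pytest.raises(ValueError, match="wt"):
            standardize(M, names=["ht", "wt", "age"])

    def test_columns_become_unit_scale(self):
        M, _ = _random_blocks(1, n=25)
        Z, _, _ = standardize(M)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_supplied_parameters_applied_not_reestimated(self):
        M, _ = _random_blocks(2)
        Z, means, scales = standardize(M)
        Znew, m2, s2 = standardize(M + 5.0, means, scales)
        np.testing.assert_allclose(Znew, Z + 5.0 / scales, atol=1e-12)
        np.testing.assert_array_equal(m2, means)


class TestExtractComponent:
    def test_single_response_weight_is_cross_product(self):
        E, F = _random_blocks(3, p=1)
        E, *_ = standardize(E)
        F, *_ = standardize(F)
        w, *_ = extract_component(E, F)
        expected = (E.T @ F).ravel()
        expected /= np.linalg.norm(expected)
        expected *= np.sign(expected[np.argmax(np.abs(expected))])
        np.testing.assert_allclose(w, expected, atol=1e-10)

    def test_exact_single_latent_direction(self):
        rng = np.random.default_rng(4)
        t_true = rng.standard_normal(15)
        a = rng.standard_normal(4)
        c = rng.standard_normal(3)
        E = np.outer(t_true, a)
        F = np.outer(t_true, c)
        w, t, u, alpha, beta = extract_component(E, F)
        resid = F - np.outer(t, beta)
        assert np.linalg.norm(resid) < 1e-10 * np.linalg.norm(F)

    def test_against_power_iteration_oracle(self):
        rng = np.random.default_rng(5)
        E = rng.standard_normal((8, 3))
        F = rng.standard_normal((8, 2))
        # oracle: power iteration on (E'F)(E'F)' then explicit projections
        M = E.T @ F
        v = np.ones(3)
        for _ in range(10_000):
            v = M @ (M.T @ v)
            v /= np.linalg.norm(v)
        v *= np.sign(v[np.argmax(np.abs(v))])
        t_o = E @ v
        alpha_o = np.linalg.lstsq(t_o[:, None], E, rcond=None)[0].ravel()
        beta_o = np.linalg.lstsq(t_o[:, None], F, rcond=None)[0].ravel()
        w, t, u, alpha, beta = extract_component(E, F)
        np.testing.assert_allclose(w, v, atol=1e-8)
        np.testing.assert_allclose(alpha, alpha_o, atol=1e-8)
        np.testing.assert_allclose(beta, beta_o, atol=1e-8)

    def test_zero_cross_covariance_signalled(self):
        E = np.zeros((6, 3))
        F = np.ones((6, 2))
        with pytest.raises(ExtractionError):
            extract_component(E, F)


class TestDeflate:
    def test_residual_orthogonal_to_score(self):
        E, F = _random_blocks(6)
        w, t, u, alpha, beta = extract_component(E, F)
        E1, F1 = deflate(E, F, t, alpha, beta)
        bound = 1e-10 * np.linalg.norm(E) * np.linalg.norm(t)
        assert np.abs(E1.T @ t).max() < bound

    def test_rank_one_block_annihilated(self):
        rng = np.random.default_rng(7)
        t = rng.standard_normal(10)
        alpha = rng.standard_normal(4)
        E = np.outer(t, alpha)
        F = np.outer(t, rng.standard_normal(2))
        w, t_hat, u, a_hat, b_hat = extract_component(E, F)
        E1, _ = deflate(E, F, t_hat, a_hat, b_hat)
        assert np.linalg.norm(E1) < 1e-10 * np.linalg.norm(E)

    def test_components_reconstruct_standardized_block(self):
        X, Y = _random_blocks(8, n=15, m=5, p=4)
        res = PLSRegression(X, Y).fit(5)
        Zx, *_ = standardize(X)
        rec = res.x_scores @ res.x_loadings.T
        # full-rank fit: accumulated rank-one terms + residual == Zx; the
        # residual E_h is Zx - rec by construction, so verify reconstruction
        E = Zx.copy()
        F, *_ = standardize(Y)
        for a in range(5):
            E, F = deflate(E, F, res.x_scores[:, a], res.x_loadings[:, a], res.y_loadings[:, a])
        np.testing.assert_allclose(rec + E, Zx, atol=1e-10)


class TestFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, m, p = 16, 4, 3
        X = rng.standard_normal((n, m))
        Y = rng.standard_normal((n, p))
        res = PLSRegression(X, Y).fit(m)
        X1 = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(X1.T @ X1, X1.T @ Y)
        ols = X1 @ beta
        rel = np.linalg.norm(res.predict(X) - ols) / np.linalg.norm(ols)
        assert rel < 1e-8

    def test_rank_one_noise_free_exact(self):
        rng = np.random.default_rng(9)
        t = rng.standard_normal(14)
        X = np.outer(t, rng.standard_normal(5)) + 10
        Y = np.outer(t, rng.standard_normal(7)) + 50
        res = PLSRegression(X, Y).fit(1)
        assert np.linalg.norm(res.resid) < 1e-8 * np.linalg.norm(Y)

    def test_component_count_bounds(self):
        X, Y = _random_blocks(10, n=6, m=5)
        model = PLSRegression(X, Y)
        assert model.max_components == 5
        with pytest.raises(ValueError):
            model.fit(0)
        with pytest.raises(ValueError):
            model.fit(6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 4))
    def test_invariants_on_random_fits(self, seed, h):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        X = rng.standard_normal((n, 5))
        Y = rng.standard_normal((n, 4))
        res = PLSRegression(X, Y).fit(h)
        # unit-norm weights
        np.testing.assert_allclose(np.linalg.norm(res.weights, axis=0), 1, atol=1e-10)
        # score orthogonality
        G = res.x_scores.T @ res.x_scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.abs(np.diag(G)).max()
        # coefficient form equals component form on training rows
        Zx, *_ = standardize(X)
        comp_pred = res.x_scores @ res.y_loadings.T * res.y_scale + res.y_mean
        np.testing.assert_allclose(
            res.predict(X), comp_pred, rtol=1e-10, atol=1e-10 * np.abs(Y).max()
        )

    def test_fit_plsr_accepts_dataset(self, default_dataset):
        res = fit_plsr(default_dataset, None, 2)
        assert res.coefficients.shape == (5, 7)


class TestPredict:
    def test_mean_row_returns_mean_response(self, default_dataset):
        res = PLSRegression.from_dataset(default_dataset).fit(2)
        pred = res.predict(default_dataset.X.mean(axis=0))
        np.testing.assert_allclose(pred, default_dataset.Y.mean(axis=0), rtol=1e-10)

    def test_training_rows_match_fittedvalues(self, default_dataset):
        res = PLSRegression.from_dataset(default_dataset).fit(3)
        np.testing.assert_array_equal(res.predict(default_dataset.X), res.fittedvalues)

    def test_finite_difference_matches_coefficients(self, default_dataset):
        res = PLSRegression.from_dataset(default_dataset).fit(2)
        x = default_dataset.X.mean(axis=0)
        for j in range(5):
            delta = 3.7
            x2 = x.copy()
            x2[j] += delta
            np.testing.assert_allclose(
                res.predict(x2) - res.predict(x),
                delta * res.coefficients[j],
                rtol=1e-8,
                atol=1e-10,
            )

    def test_wrong_column_count_rejected(self, default_dataset):
        res = PLSRegression.from_dataset(default_dataset).fit(1)
        with pytest.raises(ValueError, match="5"):
            res.predict(np.ones((2, 4)))


class TestSerialization:
    def test_text_round_trip_preserves_predictions(self, tmp_path, default_dataset):
        res = PLSRegression.from_dataset(default_dataset).fit(2)
        path = tmp_path / "model.txt"
        res.save(path)
        loaded = LoadedPLSResults.load(path)
        np.testing.assert_array_equal(loaded.coefficients, res.coefficients)
        np.testing.assert_array_equal(
            loaded.predict(default_dataset.X), res.predict(default_dataset.X)
        )

    def test_summary_mentions_shape_and_components(self, default_dataset):
        res = PLSRegression.from_dataset(default_dataset).fit(2)
        text = res.summary()
        assert "Components: 2" in text and "Y7" in text
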