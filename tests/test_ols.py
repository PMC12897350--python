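"""OLS on selected channels: normal-equations oracle, prediction, reports."""

import numpy as np
import pytest

from nirselect import (
    WavelengthGrid,
    coefficients_raw,
    fit_autoscale,
    apply_autoscale,
    fit_ols,
    model_report,
    parse_report,
    predict,
    loo_stats,
    OlsModel,
)


def _grid(p):
    return WavelengthGrid(1100, 2, p)


def normal_equations(Xs_sel, y):
    """Independent oracle: solve (A'A) b = A'y explicitly."""
    A = np.column_stack([np.ones(Xs_sel.shape[0]), Xs_sel])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestFitOls:
    def test_exact_line(self):
        x = np.linspace(-1, 1, 10)[:, None]
        m = fit_ols(x, 2.0 * x[:, 0] + 1.0, [1], grid=_grid(1))
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)

    def test_constant_response(self, rng):
        X = rng.normal(size=(12, 3))
        m = fit_ols(X, np.full(12, 4.2), [1, 3], grid=_grid(3))
        np.testing.assert_allclose(m.coefficients, 0.0, atol=1e-10)
        assert m.intercept == pytest.approx(4.2, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=30)
        m = fit_ols(X, y, [1, 2, 3, 4, 5], grid=_grid(5))
        beta = normal_equations(X, y)
        assert m.intercept == pytest.approx(beta[0], rel=1e-8)
        np.testing.assert_allclose(m.coefficients, beta[1:], rtol=1e-8)

    def test_rank_deficiency_names_channels(self, rng):
        X = rng.normal(size=(20, 4))
        X[:, 2] = X[:, 0]
        with pytest.raises(ValueError, match="nm"):
            fit_ols(X, rng.normal(size=20), [1, 3], grid=_grid(4))

    def test_residuals_orthogonal_to_columns_and_sum_zero(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=40)
        idx = [2, 4, 5]
        m = fit_ols(X, y, idx, grid=_grid(6))
        resid = y - (X[:, [i - 1 for i in idx]] @ m.coefficients + m.intercept)
        assert resid.sum() == pytest.approx(0.0, abs=1e-8)
        for i in idx:
            assert X[:, i - 1] @ resid == pytest.approx(0.0, abs=1e-7)


class TestPredict:
    def _model(self, rng, n=25, p=6):
        X_raw = rng.normal(2.0, 0.5, size=(n, p))
        scaling = fit_autoscale(X_raw)
        Xs = apply_autoscale(X_raw, scaling)
        y = Xs[:, 1] - 2.0 * Xs[:, 3] + 0.1 * rng.normal(size=n)
        m = fit_ols(Xs, y, [2, 4], scaling=scaling, grid=_grid(p))
        return m, X_raw, y

    def test_training_predictions_are_fitted_values(self, rng):
        m, X_raw, y = self._model(rng)
        cols = [i - 1 for i in m.indices]
        Xs = apply_autoscale(X_raw, m.scaling)
        np.testing.assert_allclose(predict(m, X_raw),
                                   Xs[:, cols] @ m.coefficients + m.intercept,
                                   rtol=1e-10)

    def test_column_mean_spectrum_predicts_intercept(self, rng):
        m, _, _ = self._model(rng)
        assert predict(m, m.scaling.means)[0] == pytest.approx(m.intercept,
                                                               abs=1e-10)

    def test_invariant_to_unselected_channels(self, rng):
        m, X_raw, _ = self._model(rng)
        X_pert = X_raw.copy()
        for j in range(X_raw.shape[1]):
            if (j + 1) not in m.indices:
                X_pert[:, j] += rng.normal(size=len(X_raw))
        np.testing.assert_allclose(predict(m, X_pert), predict(m, X_raw),
                                   rtol=1e-12)

    def test_grid_mismatch(self, rng):
        m, _, _ = self._model(rng)
        with pytest.raises(ValueError, match="channels"):
            predict(m, np.ones((2, 9)))


class TestCoefficientsRaw:
    def test_identity_scaling_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = fit_ols(X, y, [1, 2], grid=_grid(3))  # identity scaling default
        b_raw, a_raw = coefficients_raw(m)
        np.testing.assert_allclose(b_raw, m.coefficients)
        assert a_raw == pytest.approx(m.intercept)

    def test_halved_sd_doubles_coefficient(self, rng):
        from nirselect import ScalingParams

        m = fit_ols(rng.normal(size=(10, 1)), rng.normal(size=10), [1],
                    grid=_grid(1))
        m.scaling = ScalingParams(means=np.array([0.0]), sds=np.array([0.5]),
                                  n_fit=10)
        b_raw, _ = coefficients_raw(m)
        assert b_raw[0] == pytest.approx(2.0 * m.coefficients[0])

    def test_raw_form_reproduces_predictions(self, rng):
        X_raw = rng.normal(1.0, 0.3, size=(30, 5))
        scaling = fit_autoscale(X_raw)
        Xs = apply_autoscale(X_raw, scaling)
        y = rng.normal(size=30)
        m = fit_ols(Xs, y, [1, 3, 5], scaling=scaling, grid=_grid(5))
        b_raw, a_raw = coefficients_raw(m)
        cols = [i - 1 for i in m.indices]
        np.testing.assert_allclose(X_raw[:, cols] @ b_raw + a_raw,
                                   predict(m, X_raw), rtol=1e-8)

    def test_collinear_channels_unstable_coefficients_stable_predictions(self, rng):
        """Near-duplicate channels produce huge opposing coefficients, yet
        the predictions barely move under a tiny column perturbation."""
        n = 60
        base = rng.normal(size=n)
        X = np.column_stack([base, base + 1e-5 * rng.normal(size=n),
                             rng.normal(size=n)])
        y = base + 0.05 * rng.normal(size=n)
        m1 = fit_ols(X, y, [1, 2, 3], grid=_grid(3))
        Xp = X.copy()
        Xp[:, 1] += 1e-8 * rng.normal(size=n)
        m2 = fit_ols(Xp, y, [1, 2, 3], grid=_grid(3))
        p1 = X[:, :3] @ m1.coefficients + m1.intercept
        p2 = Xp[:, :3] @ m2.coefficients + m2.intercept
        assert np.max(np.abs(p1 - p2)) < 1e-2
        assert np.max(np.abs(m1.coefficients)) > 10.0


class TestReport:
    def _fitted(self, rng):
        X = rng.normal(size=(30, 4))
        y = X[:, 0] + 0.5 * X[:, 2] + 0.1 * rng.normal(size=30)
        m = fit_ols(X, y, [1, 3], grid=_grid(4))
        s = loo_stats(X[:, [0, 2]], y)
        return m, s

    def test_structure(self, rng):
        m, s = self._fitted(rng)
        text = model_report(m, s)
        lines = text.strip().splitlines()
        assert lines[0].startswith("(A)")
        assert len([l for l in lines if l[0].isdigit()]) == 2
        assert sum(l.startswith("Intercept") for l in lines) == 1
        assert sum(l.startswith("(B)") for l in lines) == 1
        assert len(lines) == 2 + 2 + 1 + 1 + 7

    def test_report_parse_report_byte_identical(self, rng):
        m, s = self._fitted(rng)
        text = model_report(m, s)
        parsed = parse_report(text)
        m2 = OlsModel.from_dict({
            **m.to_dict(),
            "coefficients": [r["coefficient"] for r in parsed["rows"]],
            "intercept": parsed["intercept"],
        })
        from nirselect import ModelStats
        s2 = ModelStats(**parsed["stats"])
        assert model_report(m2, s2) == text

    def test_model_json_roundtrip(self, rng):
        m, _ = self._fitted(rng)
        m2 = OlsModel.from_json(m.to_json())
        np.testing.assert_allclose(m2.coefficients, m.coefficients)
        assert m2.indices == m.indices
        X_new = rng.normal(size=(5, 4))
        np.testing.assert_allclose(predict(m2, X_new), predict(m, X_new))
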