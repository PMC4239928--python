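import numpy as np
import pytest
from scipy import stats as sps

from nirferm.chemometrics import (
    CalibrationModel,
    FitError,
    PretreatmentSpec,
    calibration_stats,
    fit_mlr,
    fit_pls,
    norris_second_derivative,
    paired_nir_lab_test,
    pca_mahalanobis_screen,
    predict,
    press_select,
)


class TestNorrisDerivative:
    SPEC = PretreatmentSpec(kind="norris_d2", segment=5, gap=5)

    def test_constant_maps_to_zero(self):
        d2, _ = norris_second_derivative(np.full(50, 3.7), self.SPEC)
        assert np.allclose(d2, 0.0)

    def test_linear_maps_to_zero(self):
        lam = np.arange(50, dtype=float)
        d2, _ = norris_second_derivative(2.0 + 0.3 * lam, self.SPEC)
        assert np.allclose(d2, 0.0, atol=1e-10)

    def test_quadratic_closed_form(self):
        # c * wavelength^2 on step h with gap g -> constant 2 c (g h)^2
        c, h, g = 0.004, 2.0, 5
        lam = 1000.0 + h * np.arange(80)
        d2, _ = norris_second_derivative(c * lam**2, self.SPEC)
        assert np.allclose(d2, 2 * c * (g * h) ** 2, rtol=1e-9)

    def test_retained_indices_annotated(self):
        spec = PretreatmentSpec(kind="norris_d2", segment=5, gap=3)
        y = np.random.default_rng(0).normal(size=40)
        d2, idx = norris_second_derivative(y, spec)
        assert idx[0] == spec.edge_width()
        assert idx[-1] == 40 - 1 - spec.edge_width()
        assert len(d2) == len(idx)

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            norris_second_derivative(np.ones(15), self.SPEC)

    def test_even_segment_rejected(self):
        with pytest.raises(ValueError):
            PretreatmentSpec(kind="norris_d2", segment=4, gap=5)

    def test_matrix_rows_match_single_rows(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 60))
        D, _ = norris_second_derivative(X, self.SPEC)
        for i in range(4):
            d, _ = norris_second_derivative(X[i], self.SPEC)
            assert np.array_equal(D[i], d)


class TestScreening:
    def test_homogeneous_set_flags_nothing(self):
        rng = np.random.default_rng(2)
        X = np.ones((50, 30)) + 1e-6 * rng.normal(size=(50, 30))
        inliers, outliers, _ = pca_mahalanobis_screen(X)
        assert len(outliers) == 0
        assert len(inliers) == 50

    def test_constructed_outlier_is_flagged(self):
        # 49 samples on a 3-factor structured model, one displaced far
        # along the first component
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(3, 40))
        scores = rng.normal(size=(50, 3))
        X = scores @ basis + 0.01 * rng.normal(size=(50, 40))
        X[17] += 12 * scores[:, 0].std() * basis[0]
        _, outliers, _ = pca_mahalanobis_screen(X)
        assert list(outliers) == [17]

    def test_chi_square_tail_fraction(self):
        # 3 structured dimensions + minuscule noise -> 3 retained PCs;
        # the flagged fraction must track P(chi2_3 > 9)
        rng = np.random.default_rng(4)
        basis = np.linalg.qr(rng.normal(size=(10, 3)))[0].T
        X = rng.normal(size=(10_000, 3)) @ basis
        X += 1e-8 * rng.normal(size=X.shape)
        _, outliers, model = pca_mahalanobis_screen(X)
        assert model.n_components == 3
        expected = sps.chi2.sf(9.0, 3)
        frac = len(outliers) / 10_000
        assert 0.5 * expected <= frac <= 2.0 * expected

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pca_mahalanobis_screen(np.ones((20, 5)))

    def test_needs_ten_samples(self):
        with pytest.raises(ValueError):
            pca_mahalanobis_screen(np.random.default_rng(0).normal(size=(5, 4)))


class TestMLR:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 19))
        beta = rng.normal(size=19)
        y = X @ beta + 4.0
        model = fit_mlr(X, y)
        assert model.training_stats.R2 == pytest.approx(1.0)
        assert np.abs(predict(model, X).values - y).max() < 1e-8

    def test_single_channel_coefficient_recovery(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(45, 19))
        y = 2.0 * X[:, 7] + 5.0 + 0.1 * rng.normal(size=45)
        model = fit_mlr(X, y)
        # OLS sampling theory: recovered coefficient within 3 standard errors
        Xc = X - X.mean(axis=0)
        cov = np.linalg.inv(Xc.T @ Xc)
        resid = y - predict(model, X).values
        s2 = resid @ resid / (45 - 19 - 1)
        se7 = np.sqrt(s2 * cov[7, 7])
        assert abs(model.coefficients[7] - 2.0) < 3 * se7

    def test_degrees_of_freedom_guard(self):
        rng = np.random.default_rng(7)
        with pytest.raises(FitError, match="n > p"):
            fit_mlr(rng.normal(size=(20, 19)), rng.normal(size=20))

    def test_rank_deficiency_refused(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 10))
        X[:, 9] = X[:, 0] + X[:, 1]  # exact collinearity
        with pytest.raises(FitError, match="rank"):
            fit_mlr(X, rng.normal(size=40))


class TestPLS:
    def test_rank_one_needs_one_factor(self):
        rng = np.random.default_rng(9)
        u = rng.normal(size=30)
        v = rng.normal(size=12)
        X = np.outer(u, v)
        y = X @ rng.normal(size=12)
        model = fit_pls(X, y, 1)
        assert np.abs(predict(model, X).values - y).max() < 1e-8

    def test_full_rank_pls_equals_ols(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = fit_pls(X, y, 5)
        design = np.column_stack([np.ones(30), X])
        ols = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.abs(predict(model, X).values - ols).max() < 1e-8 * (
            1 + np.abs(ols).max()
        )

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + 0.1 * rng.normal(size=25)
        perm = rng.permutation(25)
        m1 = fit_pls(X, y, 3)
        m2 = fit_pls(X[perm], y[perm], 3)
        assert np.abs(m1.coefficients - m2.coefficients).max() < 1e-10

    def test_matches_reference_implementation(self):
        # independent oracle: scikit-learn's NIPALS PLS
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 12))
        y = X @ rng.normal(size=12) + 0.1 * rng.normal(size=40)
        for f in (1, 3, 6):
            mine = predict(fit_pls(X, y, f), X).values
            ref = (
                sklearn.PLSRegression(n_components=f, scale=False)
                .fit(X, y)
                .predict(X)
                .ravel()
            )
            assert np.abs(mine - ref).max() < 1e-10

    def test_factor_count_bounds(self):
        rng = np.random.default_rng(13)
        with pytest.raises(FitError):
            fit_pls(rng.normal(size=(10, 5)), rng.normal(size=10), 10)

    def test_mean_spectrum_predicts_mean_reference(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 9))
        y = X @ rng.normal(size=9) + 2.0
        model = fit_pls(X, y, 4)
        pred = predict(model, X.mean(axis=0)[None, :]).values[0]
        assert pred == pytest.approx(y.mean(), abs=1e-10)


class TestPressSelect:
    def test_noiseless_rank_two_selects_two(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=(30, 2))
        X = scores @ rng.normal(size=(2, 10))
        y = scores @ np.array([1.0, -2.0])
        best, press, secv = press_select(X, y, 6)
        assert best == 2

    def test_equals_brute_force_loo_exactly(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(15, 8))
        y = X @ rng.normal(size=8) + 0.2 * rng.normal(size=15)
        best, press, secv = press_select(X, y, 5)
        brute = np.zeros(5)
        for i in range(15):
            mask = np.ones(15, dtype=bool)
            mask[i] = False
            for f in range(1, 6):
                m = fit_pls(X[mask], y[mask], f)
                brute[f - 1] += (y[i] - predict(m, X[i][None, :]).values[0]) ** 2
        assert np.array_equal(press, brute)
        assert np.allclose(secv, np.sqrt(press / 15))

    def test_selected_count_within_bounds(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        best, _, _ = press_select(X, y, 7)
        assert 1 <= best <= 7

    def test_max_factors_guard(self):
        rng = np.random.default_rng(18)
        with pytest.raises(FitError):
            press_select(rng.normal(size=(10, 5)), rng.normal(size=10), 9)


class TestStats:
    def test_perfect_prediction(self):
        s = calibration_stats(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]), 1)
        assert s.bias == 0 and s.RMSEP == 0 and s.SEP == 0
        assert s.R2 == pytest.approx(1.0)

    def test_constant_offset_bias_correction(self):
        ref = np.array([1.0, 2, 3, 4])
        s = calibration_stats(ref + 2.0, ref, 1)
        assert s.bias == pytest.approx(2.0)
        assert s.RMSEP == pytest.approx(2.0)
        assert s.SEP == pytest.approx(0.0, abs=1e-12)

    def test_three_point_worked_case(self):
        # independent spreadsheet-style recomputation, frozen
        ref = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.1, 1.9, 3.2])
        e = pred - ref
        bias = e.sum() / 3
        rmsep = np.sqrt((e**2).sum() / 3)
        sep = np.sqrt(((e - bias) ** 2).sum() / 2)
        s = calibration_stats(pred, ref, 1)
        assert s.bias == pytest.approx(bias)
        assert s.RMSEP == pytest.approx(rmsep)
        assert s.SEP == pytest.approx(sep)
        assert bias == pytest.approx(0.0666666666, rel=1e-6)
        assert rmsep == pytest.approx(0.1414213562, rel=1e-6)
        assert sep == pytest.approx(0.1527525232, rel=1e-6)

    def test_bias_correction_identity(self):
        rng = np.random.default_rng(19)
        ref = rng.normal(10, 3, size=25)
        pred = ref + rng.normal(0.5, 1.0, size=25)
        s = calibration_stats(pred, ref, 2)
        n = 25
        assert s.SEP**2 <= s.RMSEP**2 * n / (n - 1) + 1e-12

    def test_ordering_invariance(self):
        rng = np.random.default_rng(20)
        ref = rng.normal(10, 3, size=30)
        pred = ref + rng.normal(size=30)
        perm = rng.permutation(30)
        a = calibration_stats(pred, ref, 2)
        b = calibration_stats(pred[perm], ref[perm], 2)
        for f in ("R2", "bias", "SEP", "RMSEP", "SEC"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-12)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="R2"):
            calibration_stats(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]), 1)


class TestPairedTest:
    def test_identical_series(self):
        x = np.array([1.0, 2, 3])
        assert paired_nir_lab_test(x, x) == (0.0, 1.0)

    def test_textbook_differences(self):
        ref = np.zeros(3)
        pred = np.array([1.0, 2.0, 3.0])
        t, p = paired_nir_lab_test(pred, ref)
        assert t == pytest.approx(2.0 * np.sqrt(3.0))  # mean 2, sd 1, n 3
        t_ref, p_ref = sps.ttest_rel(pred, ref)
        assert t == pytest.approx(float(t_ref))
        assert p == pytest.approx(float(p_ref))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_nir_lab_test(np.array([1.0]), np.array([2.0]))

    def test_constant_nonzero_difference(self):
        t, p = paired_nir_lab_test(np.array([3.0, 4, 5]), np.array([1.0, 2, 3]))
        assert np.isinf(t) and p == 0.0


class TestModelSerialization:
    def _model(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 40))
        y = X @ rng.normal(size=40) * 0.1 + 5
        return fit_pls(X, y, 3, wavelengths=np.linspace(700, 1800, 40))

    def test_json_round_trip_is_exact(self, tmp_path):
        model = self._model()
        path = tmp_path / "model.json"
        model.to_json(str(path))
        back = CalibrationModel.from_json(str(path))
        assert np.array_equal(back.coefficients, model.coefficients)
        assert np.array_equal(back.x_mean, model.x_mean)
        assert back.y_mean == model.y_mean
        assert back.n_factors == model.n_factors
        assert back.training_range == model.training_range
        assert back.training_stats.R2 == model.training_stats.R2

    def test_round_trip_predicts_identically(self, tmp_path):
        model = self._model()
        rng = np.random.default_rng(22)
        X = rng.normal(size=(5, 40))
        back = CalibrationModel.from_json(model.to_json())
        assert np.array_equal(predict(model, X).values, predict(back, X).values)

    def test_grid_mismatch_rejected(self):
        model = self._model()
        with pytest.raises(ValueError, match="grid"):
            predict(model, np.zeros((2, 17)))

    def test_out_of_range_flagging(self):
        model = self._model()
        far = model.x_mean[None, :] + 1e3
        res = predict(model, far)
        assert res.out_of_range.dtype == bool
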