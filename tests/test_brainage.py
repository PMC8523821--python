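"""BrainAGE engine: preprocessing, PCA, RVR, LOSO estimation, bias correction."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import brainagebp as bab
from brainagebp.brainage import GAUSS_FWHM_FACTOR


class TestFwhmSigma:
    @pytest.mark.parametrize("fwhm, voxel, expected", [
        (GAUSS_FWHM_FACTOR, 1.0, 1.0),
        (0.0, 3.0, 0.0),
        (4.0, 4.0, 1.0 / GAUSS_FWHM_FACTOR),   # = 0.42466...
    ])
    def test_closed_form(self, fwhm, voxel, expected):
        assert bab.fwhm_to_sigma(fwhm, voxel) == pytest.approx(expected)

    def test_invalid_voxel(self):
        with pytest.raises(ValueError):
            bab.fwhm_to_sigma(4.0, 0.0)


class TestPreprocessVolume:
    def test_constant_volume_invariant(self):
        vol = bab.Volume(np.full((8, 8, 8), 3.5), (2.0, 2.0, 2.0))
        out = bab.preprocess_volume(vol, fwhm=4.0, target_res=4.0)
        np.testing.assert_allclose(out.data, 3.5)
        assert out.voxel_size == (4.0, 4.0, 4.0)

    def test_downsampling_shape(self):
        vol = bab.Volume(np.zeros((64, 64, 64)), (2.0, 2.0, 2.0))
        out = bab.preprocess_volume(vol, fwhm=4.0, target_res=4.0)
        assert out.data.shape == (32, 32, 32)

    def test_impulse_kernel_symmetric_peak(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0
        vol = bab.Volume(data, (4.0, 4.0, 4.0))
        out = bab.preprocess_volume(vol, fwhm=4.0, target_res=4.0)
        assert np.unravel_index(out.data.argmax(), out.data.shape) == (4, 4, 4)
        np.testing.assert_allclose(out.data, out.data[::-1, :, :], atol=1e-12)
        np.testing.assert_allclose(out.data, np.swapaxes(out.data, 0, 2),
                                   atol=1e-12)

    def test_non_integer_ratio_rejected(self):
        vol = bab.Volume(np.zeros((8, 8, 8)), (3.0, 3.0, 3.0))
        with pytest.raises(ValueError, match="integer multiple"):
            bab.preprocess_volume(vol, fwhm=4.0, target_res=4.0)

    def test_vectorize(self):
        vols = [bab.Volume(np.full((2, 2, 2), v), (4.0,) * 3) for v in (1., 2.)]
        X = bab.vectorize_volumes(vols)
        assert X.shape == (2, 8) and X[1].mean() == 2.0


def _toy_features(n=40, p=12, n_scanners=2, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i:03d}_w0" for i in range(n)], name="scan_id")
    scanner = pd.Series(
        [f"sc{i % n_scanners}" for i in range(n)], index=idx, name="scanner")
    age = pd.Series(rng.uniform(44, 76, n), index=idx, name="age")
    data = pd.DataFrame(rng.normal(size=(n, p)), index=idx)
    data.iloc[:, 0] += age.to_numpy()
    return bab.FeatureMatrix(data=data, scanner=scanner,
                             subject_id=pd.Series([f"s{i:03d}" for i in range(n)],
                                                  index=idx, name="subject_id"),
                             age=age)


class TestOrthogonalizeScanner:
    def test_residuals_uncorrelated_with_scanner(self):
        fm = _toy_features(n_scanners=3)
        out = bab.orthogonalize_scanner(fm)
        dummies = pd.get_dummies(out.scanner).to_numpy(float)
        corr = out.data.to_numpy().T @ (dummies - dummies.mean(0))
        np.testing.assert_allclose(corr, 0.0, atol=1e-8)

    def test_single_scanner_mean_centers(self):
        fm = _toy_features(n_scanners=1)
        out = bab.orthogonalize_scanner(fm)
        np.testing.assert_allclose(
            out.data.to_numpy(),
            fm.data.to_numpy() - fm.data.to_numpy().mean(0), atol=1e-10)

    def test_idempotent(self):
        fm = _toy_features()
        once = bab.orthogonalize_scanner(fm)
        twice = bab.orthogonalize_scanner(once)
        np.testing.assert_allclose(twice.data.to_numpy(),
                                   once.data.to_numpy(), atol=1e-10)

    def test_commutes_with_feature_scaling(self):
        fm = _toy_features()
        scale = np.linspace(0.5, 2.0, fm.n_features)
        scaled = bab.FeatureMatrix(data=fm.data * scale, scanner=fm.scanner,
                                   subject_id=fm.subject_id, age=fm.age)
        a = bab.orthogonalize_scanner(scaled).data.to_numpy()
        b = bab.orthogonalize_scanner(fm).data.to_numpy() * scale
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestPCA:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 15)
        X = np.outer(t, [1.0, 2.0, -3.0])
        basis = bab.fit_pca_basis(X, k=0.95)
        assert basis.k == 1
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_basis_reconstructs(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 6))
        basis = bab.fit_pca_basis(X, k=None)
        Z = basis.transform(X)
        recon = Z @ basis.components + basis.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 5))
        basis = bab.fit_pca_basis(X, k=None)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            basis.explained_variance_ratio, eig[:basis.k] / eig.sum(),
            atol=1e-10)

    def test_excess_k_clipped(self):
        X = np.random.default_rng(3).normal(size=(5, 10))
        basis = bab.fit_pca_basis(X, k=50)
        assert basis.k == 4  # min(n-1, p)

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(4).normal(size=(20, 8))
        basis = bab.fit_pca_basis(X, k=5)
        np.testing.assert_allclose(basis.components @ basis.components.T,
                                   np.eye(5), atol=1e-10)


class TestRVR:
    def test_fixed_alpha_matches_ridge_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5]) + rng.normal(0, 0.3, 30)
        alpha = 2.0
        model = bab.rvr_fit(X, y, fixed_alpha=alpha, basis="design",
                            include_bias=False)
        lam = alpha / model.beta
        ridge = np.linalg.solve(X.T @ X + lam * np.eye(4), X.T @ y)
        np.testing.assert_allclose(model.weights, ridge, atol=1e-8)

    def test_noiseless_linear_signal_interpolated(self):
        X = np.linspace(0.0, 1.0, 20).reshape(-1, 1)
        y = 2.0 * X.ravel()
        model = bab.rvr_fit(X, y, kernel="linear")
        np.testing.assert_allclose(bab.rvr_predict(model, X), y, atol=1e-6)

    def test_constant_target_gives_bias_only_model(self):
        X = np.linspace(0.0, 1.0, 10).reshape(-1, 1)
        model = bab.rvr_fit(X, np.full(10, 5.0))
        assert len(model.weights) == 0
        np.testing.assert_allclose(bab.rvr_predict(model, X), 5.0)

    def test_evidence_monotone_on_noisy_fixture(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = X @ np.array([3.0, 0.0, 0.0]) + rng.normal(0, 0.5, 50)
        model = bab.rvr_fit(X, y, kernel="linear", compute_evidence=True)
        ev = np.asarray(model.evidence_log)
        assert len(ev) > 3
        assert np.all(np.diff(ev) > -1e-9)

    def test_pruning_keeps_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = X[:, 0] * 2.0 + rng.normal(0, 0.2, 40)
        pruned = bab.rvr_fit(X, y, kernel="linear", prune=True)
        unpruned = bab.rvr_fit(X, y, kernel="linear", prune=False)
        assert len(pruned.weights) <= len(unpruned.weights)
        np.testing.assert_allclose(bab.rvr_predict(pruned, X),
                                   bab.rvr_predict(unpruned, X), atol=0.05)

    def test_duplicated_inputs_identical_predictions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 25)
        model = bab.rvr_fit(X, y)
        Xdup = np.vstack([X[:5], X[:5]])
        pred = bab.rvr_predict(model, Xdup)
        np.testing.assert_allclose(pred[:5], pred[5:])

    def test_dimension_mismatch_rejected(self):
        X = np.random.default_rng(4).normal(size=(10, 3))
        model = bab.rvr_fit(X, X[:, 0])
        with pytest.raises(ValueError, match="dimension"):
            bab.rvr_predict(model, np.zeros((2, 5)))

    def test_nonfinite_inputs_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            bab.rvr_fit(X, np.ones(5))

    def test_rbf_kernel_fits_smooth_signal(self):
        rng = np.random.default_rng(5)
        X = np.linspace(-2, 2, 60).reshape(-1, 1)
        y = np.sin(2 * X.ravel()) + rng.normal(0, 0.05, 60)
        model = bab.rvr_fit(X, y, kernel="rbf", kernel_width=0.5)
        rmse = np.sqrt(np.mean((bab.rvr_predict(model, X) - y) ** 2))
        assert rmse < 0.15

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 20)
        model = bab.rvr_fit(X, y)
        model.to_json(tmp_path / "m.json")
        back = bab.RVRModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(bab.rvr_predict(back, X),
                                   bab.rvr_predict(model, X), atol=1e-10)


def _age_signal_features(n_ma=15, n_oa=15, seed=2, noise=0.1):
    cfg = bab.SimulationConfig(n_ma=n_ma, n_oa=n_oa, feature_dim=30,
                               n_latent=1, feature_noise_sd=noise,
                               scanner_effect_size=0.0, seed=seed)
    subjects, visits = bab.build_design(cfg, seed)
    visits = bab.simulate_bp(subjects, visits, cfg, seed)
    return bab.simulate_features(visits, cfg, seed)


class TestLOSO:
    def test_no_self_inclusion(self):
        fm = _age_signal_features()
        est = bab.estimate_brainage_loso(fm, pca_k=0.95)
        # fold label must name the scan's own held-out subject, for every scan
        assert (est["fold"] == "loso_" + est["subject_id"]).all()

    def test_strong_age_signal_recovered(self):
        fm = _age_signal_features(noise=0.1)
        est = bab.estimate_brainage_loso(fm, pca_k=0.95)
        r = np.corrcoef(est["estimated_age"], est["age"])[0, 1]
        assert r > 0.9

    def test_three_subject_linear_recovery(self):
        """Hand-traceable folds: each subject's age is predicted from the
        other two alone. With the single feature equal to age, recovery is
        near-exact; the residual is the posterior shrinkage at the finite
        noise-precision optimum a 2-point fold admits."""
        idx = pd.Index(["a_w0", "b_w0", "c_w0"], name="scan_id")
        ages = pd.Series([50.0, 60.0, 70.0], index=idx, name="age")
        fm = bab.FeatureMatrix(
            data=pd.DataFrame({"f0": ages.to_numpy()}, index=idx),
            scanner=pd.Series(["sc"] * 3, index=idx, name="scanner"),
            subject_id=pd.Series(["a", "b", "c"], index=idx, name="subject_id"),
            age=ages)
        est = bab.estimate_brainage_loso(fm, pca_k=1, kernel="linear")
        np.testing.assert_allclose(est["estimated_age"], est["age"], atol=5e-3)

    def test_too_few_subjects_rejected(self):
        fm = _age_signal_features(n_ma=1, n_oa=1)
        with pytest.raises(ValueError, match="3 subjects"):
            bab.estimate_brainage_loso(fm)


class TestBiasCorrect:
    def test_perfect_estimates_give_zero(self):
        ages = np.linspace(44, 76, 20)
        out = bab.bias_correct(ages.copy(), ages)
        np.testing.assert_allclose(out["brainage"], 0.0, atol=1e-10)

    def test_affine_prediction_absorbed(self):
        ages = np.linspace(44, 76, 20)
        out = bab.bias_correct(3.0 + 1.2 * ages, ages)
        np.testing.assert_allclose(out["brainage"], 0.0, atol=1e-9)

    def test_residual_uncorrelated_with_age(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(44, 76, 100)
        est = ages + rng.normal(0, 3, 100) + 0.1 * ages
        out = bab.bias_correct(est, ages)
        assert abs(np.corrcoef(out["brainage"], ages)[0, 1]) < 1e-10

    def test_zero_age_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bab.bias_correct(np.array([1.0, 2.0, 3.0]), np.full(3, 50.0))


class TestDiagnostics:
    def test_mad_zero_for_perfect_estimates(self):
        ages = np.linspace(44, 76, 10)
        est = bab.bias_correct(ages.copy(), ages)
        assert bab.brainage_diagnostics(est)["mad_years"] == pytest.approx(0.0)

    def test_constant_offset_mad(self):
        ages = np.linspace(44, 76, 10)
        est = bab.bias_correct(ages + 1.26, ages)
        assert bab.brainage_diagnostics(est)["mad_years"] == pytest.approx(1.26)

    def test_correlation_matches_brute_force(self):
        df = pd.DataFrame({"age": [50.0, 55.0, 60.0, 65.0, 70.0],
                           "estimated_age": [53.0, 54.0, 62.0, 64.0, 71.0]})
        out = bab.bias_correct(df)
        diag = bab.brainage_diagnostics(out)
        x, y = out["brainage"].to_numpy(), out["age"].to_numpy()
        brute = (np.mean(x * y) - x.mean() * y.mean()) / (
            np.std(x) * np.std(y))
        assert diag["corr_brainage_age"] == pytest.approx(brute, abs=1e-9)
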