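"""CPM: selection, component choice, fitting, LOOCV, permutation, transfer."""

import hashlib

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

from infoflow import (
    CpmRegressor,
    external_validation,
    fit_cpm,
    loocv_internal_validation,
    permutation_test,
    predict_cpm,
    select_features,
)
from infoflow.cpm import (
    EmptySelectionError,
    TrainedCpmModel,
    choose_n_components,
    exclude_covariate_correlated,
    spearman_rho,
)


def planted_features(rng, n=20, n_features=30, n_signal=1, noise=0.1):
    """Gaussian features with behavior a noisy linear function of the first
    n_signal columns."""
    X = rng.normal(size=(n, n_features))
    signal = X[:, :n_signal].sum(axis=1)
    y = signal + noise * signal.std() * rng.normal(size=n)
    return X, y


class TestSelectFeatures:
    def test_perfectly_correlated_feature_selected(self, rng):
        y = rng.normal(size=10)
        X = np.column_stack([y, rng.normal(size=10)])
        mask = select_features(X, y, alpha=0.05)
        assert mask[0]

    def test_constant_feature_never_selected(self, rng):
        y = rng.normal(size=10)
        X = np.column_stack([np.full(10, 3.0), y])
        mask = select_features(X, y, alpha=0.05)
        assert not mask[0] and mask[1]

    def test_matches_scipy_spearmanr(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        mask = select_features(X, y, alpha=0.3)
        for j in range(8):
            p = stats.spearmanr(X[:, j], y).pvalue
            assert mask[j] == (p <= 0.3)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="4 subjects"):
            select_features(rng.normal(size=(3, 2)), rng.normal(size=3))

    def test_null_type_one_calibration(self):
        """Mean selected fraction of pure-noise features ~ alpha."""
        fractions = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            X = rng.normal(size=(20, 500))
            y = rng.normal(size=20)
            fractions.append(select_features(X, y, alpha=0.05).mean())
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.02)


class TestCovariateExclusion:
    def test_feature_equal_to_covariate_excluded(self, rng):
        cov = rng.normal(size=(12, 1))
        X = np.column_stack([cov[:, 0], rng.normal(size=12)])
        keep = exclude_covariate_correlated(X, cov, alpha=0.05)
        assert not keep[0] and keep[1]

    def test_zero_width_covariates_keep_all(self, rng):
        X = rng.normal(size=(10, 4))
        keep = exclude_covariate_correlated(X, np.empty((10, 0)), alpha=0.05)
        assert keep.all()

    def test_independent_exclusion_rate(self):
        """Three independent covariates: exclusion rate ~ 1 - (1-alpha)^3."""
        rates = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(20, 50))
            cov = rng.normal(size=(20, 3))
            rates.append(1.0 - exclude_covariate_correlated(X, cov, 0.05).mean())
        assert np.mean(rates) == pytest.approx(1 - 0.95**3, abs=0.05)

    def test_misaligned_covariates_rejected(self, rng):
        with pytest.raises(ValueError, match="misaligned"):
            exclude_covariate_correlated(
                rng.normal(size=(10, 3)), rng.normal(size=(9, 1))
            )


class TestChooseComponents:
    def test_exact_linear_signal_recovers_rho_one(self, rng):
        n = 12
        f = rng.normal(size=n)
        X = np.column_stack([f] + [rng.normal(size=n) * 0.01 for _ in range(5)])
        y = 3.0 * f + 1.0
        from infoflow.cpm import _choose_from_predictions, _inner_loocv_predictions

        preds = _inner_loocv_predictions(X, y, min(n - 1, X.shape[1]))
        c, rhos = _choose_from_predictions(preds, y)
        assert rhos[c - 1] == pytest.approx(1.0)

    def test_candidate_count_bounded_by_subjects(self, rng):
        X = rng.normal(size=(5, 10))
        y = rng.normal(size=5)
        assert 1 <= choose_n_components(X, y) <= 4

    def test_two_factor_cohort_prefers_at_least_two_components(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            n = 20
            f1, f2 = rng.normal(size=(2, n))
            load = np.zeros((30, 2))
            load[:15, 0] = 1.0
            load[15:, 1] = 1.0
            X = np.column_stack([f1, f2]) @ load.T + 0.05 * rng.normal(size=(n, 30))
            y = f1 + f2
            if choose_n_components(X, y) >= 2:
                hits += 1
        assert hits >= 40  # >= 80% of replicates

    def test_no_selected_features_rejected(self, rng):
        with pytest.raises(EmptySelectionError):
            choose_n_components(np.empty((10, 0)), rng.normal(size=10))


class TestFitPredict:
    def test_noiseless_cohort_fits_training_ranks_exactly(self, rng):
        X, y = planted_features(rng, noise=0.0)
        model = fit_cpm(X, y)
        raw, _ = predict_cpm(model, X)
        assert spearman_rho(raw, y) == pytest.approx(1.0)

    def test_single_feature_matches_simple_regression(self, rng):
        n = 10
        x = rng.normal(size=n)
        y = 2.0 * x + 0.5 + 0.01 * rng.normal(size=n)
        model = fit_cpm(x[:, None], y)
        # one component == the centered feature direction; OLS closed form
        scores = (x - x.mean()) * model.pca_loadings[0, 0]
        slope = ((scores - scores.mean()) @ (y - y.mean())) / (
            (scores - scores.mean()) ** 2
        ).sum()
        intercept = y.mean() - slope * scores.mean()
        assert model.regression_coefficients[0] == pytest.approx(slope)
        assert model.regression_intercept == pytest.approx(intercept)

    def test_train_pred_sd_positive(self, rng):
        X, y = planted_features(rng)
        assert fit_cpm(X, y).train_pred_sd > 0

    def test_matches_sklearn_pca_regression(self, rng):
        """Dual route: same mask and component count, sklearn PCA + OLS."""
        X, y = planted_features(rng, n=16, n_features=12, n_signal=2, noise=0.3)
        model = fit_cpm(X, y)
        Xs = X[:, model.selected_mask]
        ref = PCA(n_components=model.n_components).fit(Xs)
        scores = ref.transform(Xs)
        reg = LinearRegression().fit(scores, y)
        expected = reg.predict(ref.transform(Xs))
        raw, _ = predict_cpm(model, X)
        assert np.allclose(raw, expected, atol=1e-8)

    def test_prediction_of_training_row_is_fitted_value(self, rng):
        X, y = planted_features(rng, n=12, noise=0.2)
        model = fit_cpm(X, y)
        raw_all, _ = predict_cpm(model, X)
        raw_one, _ = predict_cpm(model, X[4])
        assert raw_one[0] == pytest.approx(raw_all[4])

    def test_z_is_centered_affine_of_raw(self, rng):
        X, y = planted_features(rng)
        model = fit_cpm(X, y)
        raw, z = predict_cpm(model, X)
        assert np.allclose(
            z, (raw - model.train_pred_mean) / model.train_pred_sd
        )
        # order preserving on any batch
        assert np.array_equal(np.argsort(raw), np.argsort(z))
        # raw at the training mean maps to z = 0
        assert spearman_rho(raw, z) == pytest.approx(1.0)

    def test_wrong_feature_count_rejected(self, rng):
        X, y = planted_features(rng)
        model = fit_cpm(X, y)
        with pytest.raises(ValueError, match="expected"):
            predict_cpm(model, X[:, :-1])

    def test_empty_selection_raises(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        with pytest.raises(EmptySelectionError):
            fit_cpm(X, y, alpha=1e-9)

    def test_model_roundtrips_through_dict(self, rng):
        X, y = planted_features(rng)
        model = fit_cpm(X, y, feature_labels=[f"f{i}" for i in range(X.shape[1])])
        clone_ = TrainedCpmModel.from_dict(model.to_dict())
        raw1, z1 = predict_cpm(model, X)
        raw2, z2 = predict_cpm(clone_, X)
        assert np.allclose(raw1, raw2) and np.allclose(z1, z2)


class TestLoocv:
    def test_fold_hygiene_audit(self, rng):
        """Left-out subject's data appears nowhere in its fold's training
        inputs, and each fold equals an independent refit without it."""
        X, y = planted_features(rng, n=12, noise=0.3)
        res = loocv_internal_validation(X, y)
        for fold in res.folds:
            i = fold.test_index
            assert i not in fold.train_indices
            tr = np.arange(len(y)) != i
            expect = hashlib.sha256()
            expect.update(np.ascontiguousarray(X[tr]).tobytes())
            expect.update(np.ascontiguousarray(y[tr]).tobytes())
            assert fold.train_checksum == expect.hexdigest()
            ref = fit_cpm(X[tr], y[tr])
            assert np.array_equal(fold.selected_mask, ref.selected_mask)
            assert fold.n_components == ref.n_components
            raw, z = predict_cpm(ref, X[i])
            assert fold.raw_prediction == pytest.approx(raw[0])
            assert fold.z_prediction == pytest.approx(z[0])

    def test_perturbing_left_out_subject_leaves_its_fold_unchanged(self, rng):
        X, y = planted_features(rng, n=12, noise=0.3)
        res1 = loocv_internal_validation(X, y)
        X2 = X.copy()
        X2[5] += 100.0  # wild perturbation of one subject's features only
        res2 = loocv_internal_validation(X2, y)
        f1 = res1.folds[5]
        f2 = res2.folds[5]
        assert np.array_equal(f1.selected_mask, f2.selected_mask)
        assert f1.n_components == f2.n_components
        assert f1.raw_prediction != f2.raw_prediction  # prediction does change

    def test_strong_planted_effect_recovered(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            X, y = planted_features(rng, n=20, n_features=16, noise=0.1)
            if loocv_internal_validation(X, y).rho > 0.5:
                hits += 1
        assert hits >= 9

    def test_null_cohorts_centered_near_zero(self):
        """Under the null the LOOCV rho is widely spread (fold predictions
        share selected features) but must be *centered* near zero — any
        leakage of the left-out subject would shift the mean positive."""
        rhos = []
        for rep in range(50):
            rng = np.random.default_rng(10_000 + rep)
            X = rng.normal(size=(20, 16))
            y = rng.normal(size=20)
            r = loocv_internal_validation(X, y, on_empty_selection="mean").rho
            rhos.append(0.0 if np.isnan(r) else r)
        assert abs(np.mean(rhos)) < 0.25
        assert np.mean(np.abs(rhos)) < 0.6

    def test_subject_order_invariance(self, rng):
        X, y = planted_features(rng, n=14, noise=0.2)
        perm = rng.permutation(14)
        r1 = loocv_internal_validation(X, y)
        r2 = loocv_internal_validation(X[perm], y[perm])
        assert np.allclose(r2.z_scores, r1.z_scores[perm])
        assert r2.rho == pytest.approx(r1.rho)

    def test_empty_selection_policy(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(EmptySelectionError, match="fold"):
            loocv_internal_validation(X, y, alpha=1e-12)
        res = loocv_internal_validation(
            X, y, alpha=1e-12, on_empty_selection="mean"
        )
        assert np.all(res.z_scores == 0)

    def test_power_increases_as_noise_falls(self):
        mean_rho = []
        for noise in (2.0, 0.1):
            rhos = []
            for rep in range(10):
                rng = np.random.default_rng(500 + rep)
                X, y = planted_features(rng, n=20, n_features=16, noise=noise)
                rhos.append(loocv_internal_validation(
                    X, y, on_empty_selection="mean").rho)
            mean_rho.append(np.nanmean(rhos))
        assert mean_rho[-1] > mean_rho[0]


class TestPermutation:
    def test_noiseless_cohort_attains_minimum_p(self, rng):
        # per-fold z-scoring means the observed rho is near (not exactly) 1;
        # no permutation beats it, so p hits the attainable minimum
        X, y = planted_features(rng, n=12, n_features=8, noise=0.0)
        res = permutation_test(X, y, n_iterations=99, seed=0)
        assert res.observed_rho > 0.9
        assert res.observed_rho > res.null_rhos.max()
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_deterministic_given_seed(self, rng):
        X, y = planted_features(rng, n=10, n_features=6, noise=0.5)
        a = permutation_test(X, y, n_iterations=50, seed=7)
        b = permutation_test(X, y, n_iterations=50, seed=7)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_rhos, b.null_rhos)

    def test_null_data_gives_large_p(self):
        rng = np.random.default_rng(77)
        X = rng.normal(size=(14, 10))
        y = rng.normal(size=14)
        res = permutation_test(X, y, n_iterations=99, seed=1)
        assert res.p_value > 0.05


class TestExternalValidation:
    def test_transfer_to_cohort_from_same_process(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            n_tr, n_te, f = 20, 15, 16
            Xtr = rng.normal(size=(n_tr, f))
            Xte = rng.normal(size=(n_te, f))
            ytr = Xtr[:, 0] + 0.1 * rng.normal(size=n_tr)
            yte = Xte[:, 0] + 0.1 * rng.normal(size=n_te)
            _, rho = external_validation(Xtr, ytr, Xte, test_y=yte)
            if rho is not None and rho > 0:
                hits += 1
        assert hits >= 18  # >= 90%

    def test_negated_test_behavior_flips_sign(self, rng):
        X, y = planted_features(rng, n=20, n_features=16, noise=0.1)
        Xte = rng.normal(size=(10, 16))
        yte = Xte[:, 0]
        z1, rho1 = external_validation(X, y, Xte, test_y=yte)
        z2, rho2 = external_validation(X, y, Xte, test_y=-yte)
        assert np.array_equal(z1, z2)
        assert rho2 == pytest.approx(-rho1)

    def test_single_test_subject_returns_z_only(self, rng):
        X, y = planted_features(rng)
        z, rho = external_validation(X, y, X[3], test_y=np.array([1.0]))
        assert z.shape == (1,)
        assert rho is None


class TestSpearmanRho:
    def test_invariant_under_increasing_transform(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        assert spearman_rho(np.exp(a), b) == pytest.approx(spearman_rho(a, b))

    def test_matches_scipy_with_ties(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 6.0, 5.0])
        assert spearman_rho(a, b) == pytest.approx(stats.spearmanr(a, b).statistic)

    def test_constant_input_is_nan(self):
        assert np.isnan(spearman_rho(np.ones(5), np.arange(5.0)))


class TestCpmRegressor:
    def test_sklearn_protocol(self, rng):
        X, y = planted_features(rng)
        reg = CpmRegressor(alpha=0.1)
        assert reg.get_params() == {"alpha": 0.1}
        reg2 = clone(reg).set_params(alpha=0.05)
        assert reg2.alpha == 0.05
        reg.fit(X, y)
        assert reg.n_features_in_ == X.shape[1]
        assert reg.selected_mask_.any()
        assert reg.predict(X).shape == (len(y),)
        assert reg.predict_z(X).shape == (len(y),)

    def test_unfitted_predict_raises(self, rng):
        with pytest.raises(AttributeError, match="not fitted"):
            CpmRegressor().predict(rng.normal(size=(3, 4)))

    def test_facade_matches_functions(self, rng):
        X, y = planted_features(rng)
        reg = CpmRegressor().fit(X, y)
        model = fit_cpm(X, y)
        raw_f, z_f = predict_cpm(model, X)
        assert np.allclose(reg.predict(X), raw_f)
        assert np.allclose(reg.predict_z(X), z_f)
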