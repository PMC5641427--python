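"""Covariance PCA, loadings, PC-axis reconstruction, abnormality filter."""

import numpy as np
import pytest

from spermshape.efd import contour_aspect_ratio, flatten_coeffs
from spermshape.pca import (biplot_arrow_lengths, coefficient_names,
                            factor_loadings, filter_abnormal, pca_fit,
                            reconstruct_along_pc)
from spermshape.synthetic import PopulationSpec, sample_population


def population_matrix(spec: PopulationSpec, n_harmonics: int = 20):
    from spermshape.efd import efd_estimate, efd_normalize

    recs = sample_population(spec, n_harmonics)
    X = np.array([flatten_coeffs(efd_normalize(
        efd_estimate(r.contour, n_harmonics))) for r in recs])
    ids = [r.specimen_id for r in recs]
    return X, ids, recs


@pytest.fixture(scope="module")
def planted_population():
    return population_matrix(PopulationSpec(n_specimens=120, rng_seed=11))


class TestFit:
    def test_planar_points_closed_form_rates(self):
        # 4 points at (+-1, 0), (0, +-0.5) in a 10-D space: covariance
        # eigenvalues are 2/3 and 1/6 (hand eigen-decomposition), so the
        # contribution rates are 0.8 and 0.2
        X = np.zeros((4, 10))
        X[0, 0], X[1, 0] = 1.0, -1.0
        X[2, 1], X[3, 1] = 0.5, -0.5
        model, scores = pca_fit(X)
        assert model.eigenvalues[0] == pytest.approx(2 / 3)
        assert model.eigenvalues[1] == pytest.approx(1 / 6)
        assert model.contribution_rates[:2] == pytest.approx([0.8, 0.2])

    def test_rates_sum_to_one(self, rng):
        X = rng.normal(size=(30, 9))
        model, _ = pca_fit(X)
        assert model.contribution_rates.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_rows_preserve_decomposition(self, rng):
        X = rng.normal(size=(25, 7))
        m1, _ = pca_fit(X)
        m2, _ = pca_fit(np.vstack([X, X]))
        assert np.allclose(np.abs(m1.eigenvectors), np.abs(m2.eigenvectors),
                           atol=1e-8)
        assert np.allclose(m1.contribution_rates, m2.contribution_rates,
                           atol=1e-10)

    def test_score_columns_centered_and_decorrelated(self, planted_population):
        X, ids, _ = planted_population
        model, scores = pca_fit(X, ids)
        S = scores.to_numpy()
        assert np.abs(S.mean(axis=0)).max() < 1e-9
        cov = S.T @ S / (S.shape[0] - 1)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9
        assert np.allclose(np.diag(cov), model.eigenvalues, atol=1e-9)

    def test_sign_conventions(self, planted_population):
        X, ids, _ = planted_population
        model, _ = pca_fit(X, ids)
        assert model.eigenvectors[0, 0] >= 0          # d1 entry of PC1
        for k in range(1, 6):
            col = model.eigenvectors[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_matches_sklearn_cross_check(self, planted_population):
        from sklearn.decomposition import PCA as SkPCA

        X, _, _ = planted_population
        model, scores = pca_fit(X)
        sk = SkPCA(n_components=5).fit(X)
        assert np.allclose(model.eigenvalues[:5], sk.explained_variance_,
                           rtol=1e-8)
        assert np.allclose(model.contribution_rates[:5],
                           sk.explained_variance_ratio_, rtol=1e-8)
        for k in range(3):
            dot = abs(model.eigenvectors[:, k] @ sk.components_[k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_nan_rows_reported(self):
        X = np.ones((5, 4)) + np.arange(5)[:, None]
        X[2, 1] = np.nan
        with pytest.raises(ValueError, match="s0002"):
            pca_fit(X)


class TestLoadings:
    def test_variable_equal_to_score_loads_one(self, rng):
        z = rng.normal(size=40)
        X = np.column_stack([z, 0.1 * rng.normal(size=40)])
        model, scores = pca_fit(X, d1_index=0)
        L = factor_loadings(model, X)
        assert abs(L.iloc[0, 0]) == pytest.approx(1.0, abs=1e-2)

    def test_loadings_bounded_by_one(self, planted_population):
        X, _, _ = planted_population
        model, _ = pca_fit(X)
        L = factor_loadings(model, X).to_numpy()
        assert np.abs(L).max() <= 1.0 + 1e-12

    def test_d1_dominates_pc1_loadings(self, planted_population):
        X, _, _ = planted_population
        model, _ = pca_fit(X)
        L = factor_loadings(model, X)["PC1"].to_numpy()
        assert abs(L[0]) >= 2.0 * np.abs(L[1:]).max()

    def test_zero_variance_variable_warns(self, rng):
        X = rng.normal(size=(20, 4))
        X[:, 2] = 3.14
        model, _ = pca_fit(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            L = factor_loadings(model, X)
        assert (L.iloc[2] == 0).all()

    def test_arrow_lengths_and_display_flags(self, planted_population):
        X, _, _ = planted_population
        model, _ = pca_fit(X)
        L = factor_loadings(model, X)
        arrows = biplot_arrow_lengths(L)
        expect = np.hypot(L["PC1"], L["PC2"])
        assert np.allclose(arrows["arrow_length"], expect)
        assert (arrows["display"] == (expect > 0.1)).all()


class TestReconstructAlongPC:
    def test_k_zero_gives_mean_shape(self, planted_population):
        from spermshape.efd import efd_reconstruct, unflatten_coeffs

        X, _, _ = planted_population
        model, _ = pca_fit(X)
        contour = reconstruct_along_pc(model, 1, 0.0)
        expect = efd_reconstruct(unflatten_coeffs(model.mean_vector),
                                 n_points=contour.shape[0])
        assert np.allclose(contour, expect)
        # re-measured d1 of the synthesized mean shape tracks the mean
        # coefficient up to the arc-length reparameterization bias
        assert contour_aspect_ratio(contour) == pytest.approx(
            model.mean_vector[0], abs=2e-4)

    def test_plus_minus_symmetric_about_mean(self, planted_population):
        X, _, _ = planted_population
        model, _ = pca_fit(X)
        lam = np.sqrt(model.eigenvalues[0])
        hi = model.mean_vector + 2 * lam * model.eigenvectors[:, 0]
        lo = model.mean_vector - 2 * lam * model.eigenvectors[:, 0]
        assert np.allclose((hi + lo) / 2, model.mean_vector)

    def test_d1_gap_matches_linear_algebra(self, planted_population):
        # the displaced coefficient vectors differ by exactly
        # 4 sqrt(lambda1) e_1 (linear algebra); the re-measured contour
        # d1 gap agrees up to the reparameterization bias
        X, _, _ = planted_population
        model, _ = pca_fit(X)
        expect_vec = 4 * np.sqrt(model.eigenvalues[0]) * model.eigenvectors[:, 0]
        hi = model.mean_vector + expect_vec / 2
        lo = model.mean_vector - expect_vec / 2
        assert np.allclose(hi - lo, expect_vec)
        d_hi = reconstruct_along_pc(model, 1, 2.0)
        d_lo = reconstruct_along_pc(model, 1, -2.0)
        gap = contour_aspect_ratio(d_hi) - contour_aspect_ratio(d_lo)
        assert gap == pytest.approx(abs(expect_vec[0]), rel=0.1)

    def test_bounds_validation(self, planted_population):
        X, _, _ = planted_population
        model, _ = pca_fit(X)
        with pytest.raises(ValueError):
            reconstruct_along_pc(model, 0, 1.0)
        with pytest.raises(ValueError):
            reconstruct_along_pc(model, 1, 3.5)


class TestAbnormalityFilter:
    def test_homogeneous_population_nothing_excluded(self):
        X, ids, _ = population_matrix(PopulationSpec(n_specimens=60,
                                                     rng_seed=21))
        result = filter_abnormal(X, ids)
        assert result.abnormal_ids == []
        assert result.normal_matrix.shape == X.shape

    def test_planted_abnormals_recovered(self):
        X, ids, recs = population_matrix(PopulationSpec(
            n_specimens=100, abnormal_fraction=0.1, rng_seed=31))
        truth = {r.specimen_id for r in recs if r.is_abnormal}
        result = filter_abnormal(X, ids)
        found = set(result.abnormal_ids)
        assert len(truth & found) >= 0.95 * len(truth)
        assert len(found - truth) <= 0.02 * (len(ids) - len(truth))

    def test_infinite_threshold_is_noop(self):
        X, ids, _ = population_matrix(PopulationSpec(n_specimens=30,
                                                     rng_seed=4))
        result = filter_abnormal(X, ids, threshold=np.inf)
        assert result.normal_ids == ids
        assert np.array_equal(result.normal_matrix, X)

    def test_pass2_mean_d1_matches_arithmetic_mean(self):
        X, ids, _ = population_matrix(PopulationSpec(n_specimens=40,
                                                     rng_seed=6))
        result = filter_abnormal(X, ids)
        assert result.pass2_model.mean_vector[0] == pytest.approx(
            result.normal_matrix[:, 0].mean(), abs=1e-12)

    def test_all_excluded_raises(self):
        X = np.eye(4) * 5 + 1
        with pytest.raises(ValueError):
            filter_abnormal(X, threshold=-100.0)


def test_coefficient_names_layout():
    names = coefficient_names(77)
    assert names[0] == "d1"
    assert names[1:5] == ["a2", "b2", "c2", "d2"]
    assert names[-1] == "d20"
    with pytest.raises(ValueError):
        coefficient_names(10)
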