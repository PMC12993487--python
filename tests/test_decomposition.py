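"""Effect-matrix decomposition, explained variance and per-effect PCA."""

import numpy as np
import pytest

from conftest import positive_tweedie_table, random_balanced_design
from glmasca import (
    GLMASCA,
    augmented_scores,
    combine_effects,
    effect_pca,
)
from glmasca.design import FactorSpec, build_design
from glmasca.model import EffectMatrix


@pytest.fixture
def fitted_2x2(design_2x2, rng):
    Y = positive_tweedie_table(design_2x2, rng, p=7)
    return GLMASCA(Y, design_2x2, rho=1.5).fit()


class TestDecomposition:
    def test_working_identity(self, fitted_2x2):
        X = fitted_2x2.design.X
        assert np.allclose(
            fitted_2x2.Z, X @ fitted_2x2.B + fitted_2x2.R_w, atol=1e-10
        )

    def test_effect_matrix_sum_reconstructs_working_response(self, fitted_2x2):
        total = sum(m.M for m in fitted_2x2.effect_matrices())
        assert np.max(np.abs(total + fitted_2x2.R_w - fitted_2x2.Z)) < 1e-10

    def test_intercept_rows_identical(self, fitted_2x2):
        M0 = fitted_2x2.effect_matrix("(intercept)").M
        assert np.allclose(M0, M0[0])

    def test_orthogonality_gap_small(self, fitted_2x2):
        rep = fitted_2x2.verify_orthogonality(tol=1e-8)
        assert rep["relative_gap"] < 1e-8

    def test_unbalanced_design_breaks_orthogonality(self, design_2x2, rng):
        # drop the last sample: one cell has 2 replicates instead of 3
        Y = positive_tweedie_table(design_2x2, rng, p=5)[:11]
        a = ["a1"] * 6 + ["a2"] * 5
        b = (["b1"] * 3 + ["b2"] * 3) + (["b1"] * 3 + ["b2"] * 2)
        d = build_design(
            [FactorSpec("A", ["a1", "a2"], a), FactorSpec("B", ["b1", "b2"], b)],
            interactions="all",
        )
        with pytest.warns(UserWarning):
            res = GLMASCA(Y, d, rho=1.5).fit()
            rep = res.verify_orthogonality(tol=1e-8)
        assert rep["relative_gap"] > 1e-8

    def test_gaussian_identity_equals_classical_asca(self, design_2x2, rng):
        # OLS working response is the data itself; effect matrices are the
        # classical cell-mean contrasts
        Y = rng.normal(10, 2, size=(design_2x2.n, 5))
        res = GLMASCA(Y, design_2x2, family="gaussian", link="identity").fit()
        assert np.allclose(res.Z, Y)
        X = design_2x2.X
        P = X @ np.linalg.solve(X.T @ X, X.T)
        fitted = P @ Y
        total = sum(m.M for m in res.effect_matrices())
        assert np.allclose(total, fitted, atol=1e-8)
        rep = res.verify_orthogonality(tol=1e-10)
        assert rep["relative_gap"] < 1e-10

    def test_percent_variation_sums_to_100(self, fitted_2x2):
        pv = fitted_2x2.percent_variation()
        assert pv["percent_variation"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_feature_reduces_to_univariate(self, design_2x2, rng):
        from glmasca.tweedie import irls_fit

        Y = positive_tweedie_table(design_2x2, rng, p=1)
        res = GLMASCA(Y, design_2x2, rho=1.5).fit()
        uni = irls_fit(Y[:, 0], design_2x2.X, rho=1.5)
        assert np.allclose(res.B[:, 0], uni.beta, atol=1e-8)

    def test_offset_rejected(self, design_2x2, rng):
        Y = positive_tweedie_table(design_2x2, rng, p=2)
        with pytest.raises(ValueError, match="offset"):
            GLMASCA(Y, design_2x2, rho=1.5, offset=np.ones(design_2x2.n))


class TestFamilies:
    @pytest.mark.parametrize("family,link", [
        ("poisson", "log"), ("gamma", "log"), ("gaussian", "identity"),
    ])
    def test_orthogonality_across_families(self, design_2x2, rng, family, link):
        Y = positive_tweedie_table(design_2x2, rng, p=6) + 0.5
        res = GLMASCA(Y, design_2x2, family=family, link=link).fit()
        assert res.verify_orthogonality(tol=1e-8)["relative_gap"] < 1e-8

    def test_gamma_log_unit_weights_orthogonal_without_saturation(self, rng):
        # rho=2 with log link gives constant weights, so balance alone
        # suffices even for an unsaturated (main-effects-only) model
        f1 = FactorSpec("A", ["a", "b"], ["a"] * 6 + ["b"] * 6)
        f2 = FactorSpec("B", ["x", "y"], (["x"] * 3 + ["y"] * 3) * 2)
        d = build_design([f1, f2], interactions="none")
        Y = np.exp(rng.normal(2, 0.5, size=(12, 5)))
        with pytest.warns(UserWarning):  # unsaturated warning
            res = GLMASCA(Y, d, family="gamma", link="log", tol=1e-14, max_iter=300).fit()
        assert res.verify_orthogonality(tol=1e-8)["relative_gap"] < 1e-8


class TestEffectPCA:
    def test_rank_one_matrix_single_component(self):
        M = EffectMatrix("toy", np.outer([1.0, -1, 1, -1], [2.0, 0, 1]))
        pca = effect_pca(M, q="full")
        assert pca.q == 1
        assert pca.component_variance[0] == pytest.approx(1.0)

    def test_full_rank_exact_reconstruction(self, rng):
        M = EffectMatrix("toy", rng.normal(size=(6, 4)))
        pca = effect_pca(M, q="full")
        assert np.allclose(pca.scores @ pca.loadings.T, M.M, atol=1e-10)
        assert np.allclose(pca.loadings.T @ pca.loadings, np.eye(pca.q), atol=1e-10)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            effect_pca(EffectMatrix("z", np.zeros((4, 3))))

    def test_var80_rule(self):
        # singular values 3,1,... shares 0.9/0.1 -> q=1
        M = np.diag([3.0, 1.0])
        pca = effect_pca(EffectMatrix("d", M), q="var80")
        assert pca.q == 1

    def test_augmented_scores_reduce_to_scores_without_residuals(self, rng):
        A = rng.normal(size=(6, 4))
        pca = effect_pca(EffectMatrix("toy", A), q="full")
        aug = augmented_scores(EffectMatrix("toy", A), np.zeros_like(A), pca.loadings)
        assert np.allclose(aug, pca.scores, atol=1e-10)

    def test_projection_contraction(self, rng):
        A, R = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        pca = effect_pca(EffectMatrix("toy", A), q="full")
        aug = augmented_scores(EffectMatrix("toy", A), R, pca.loadings)
        assert np.linalg.norm(aug) <= np.linalg.norm(A + R) + 1e-12

    def test_replicate_mean_augmented_scores_near_cell_scores(self, fitted_2x2):
        pca = fitted_2x2.pca("A", q="full")
        cells = np.array([hash(c) for c in fitted_2x2.design.cells])
        for c in np.unique(cells):
            mask = cells == c
            assert np.allclose(
                pca.augmented_scores[mask].mean(axis=0),
                pca.scores[mask].mean(axis=0),
                atol=2.0,  # Monte-Carlo scatter of replicate residuals
            )


class TestCombineEffects:
    def test_combining_with_zero_returns_original(self, rng):
        A = EffectMatrix("A", rng.normal(size=(5, 3)))
        Z = EffectMatrix("Z", np.zeros((5, 3)))
        comb = combine_effects([A, Z])
        assert np.allclose(comb.M, A.M)
        assert comb.label == "A+Z"

    def test_norm_additivity_under_block_orthogonality(self, fitted_2x2):
        MA = fitted_2x2.effect_matrix("A")
        MAB = fitted_2x2.effect_matrix("A:B")
        comb = combine_effects([MA, MAB])
        assert np.sum(comb.M**2) == pytest.approx(
            np.sum(MA.M**2) + np.sum(MAB.M**2), rel=1e-10
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            combine_effects(
                [EffectMatrix("A", rng.normal(size=(4, 3))),
                 EffectMatrix("B", rng.normal(size=(5, 3)))]
            )


def test_orthogonality_property_random_designs(rng):
    """Random balanced saturated designs keep the decomposition exact."""
    for _ in range(8):
        d = random_balanced_design(rng)
        Y = positive_tweedie_table(d, rng, p=4)
        res = GLMASCA(Y, d, rho=float(rng.uniform(1.2, 1.8))).fit()
        assert res.verify_orthogonality(tol=1e-8)["relative_gap"] < 1e-8
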