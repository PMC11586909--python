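"""Latent BLUPs, curve prediction, latent FPCA and scores."""

import numpy as np
import pytest
from scipy.linalg import eig as dense_eig

from fsgc.data import to_grid_matrix
from fsgc.kendall import sample_tau
from fsgc.latent import (blup_matrix, fpca_scores, gibbs_blup, latent_fpca,
                         predict_curve, score_distance)
from fsgc.marginals import estimate_cutoffs, estimate_transform
from fsgc.simulate import KernelSpec, ScenarioSpec, simulate_glnpp

from conftest import make_dataset


class TestBlup:
    def test_balanced_binary_at_independence(self):
        # X = 1, cutoff 0, identity correlation: E[V|V>0] = sqrt(2/pi)
        ds = make_dataset(np.array([[1.0, 0.0]]), kind="binary")
        cut = estimate_cutoffs(
            make_dataset(np.array([[1.0, 1.0], [0.0, 0.0]]), kind="binary"))
        V = blup_matrix(ds, np.eye(2), cut, None)
        assert V[0, 0] == pytest.approx(np.sqrt(2 / np.pi), abs=1e-10)
        assert V[0, 1] == pytest.approx(-np.sqrt(2 / np.pi), abs=1e-10)

    def test_symmetric_middle_cell_is_zero(self):
        # ordinal category with latent cell (-c, c) has conditional mean 0
        X = np.array([[1.0], [0.0], [2.0], [1.0]])
        ds = make_dataset(X, kind="ordinal", levels=3)
        cut = estimate_cutoffs(ds)
        assert cut.cutoffs[0, 0] == pytest.approx(-cut.cutoffs[0, 1])
        V = blup_matrix(ds, np.eye(1), cut, None)
        assert V[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_continuous_blup_is_the_transform(self, rng):
        x = rng.normal(size=(10, 3))
        ds = make_dataset(x)
        tr = estimate_transform(ds)
        C = np.array([[1, 0.5, 0.2], [0.5, 1, 0.5], [0.2, 0.5, 1.0]])
        V = blup_matrix(ds, C, None, tr)
        for j in range(3):
            np.testing.assert_allclose(V[:, j], tr(j, x[:, j]), atol=1e-14)

    def test_two_stage_close_to_gibbs_oracle(self):
        # m = 5, compound symmetry rho = 0.6, binary data, 50 subjects
        m, rho = 5, 0.6
        C = np.full((m, m), rho)
        np.fill_diagonal(C, 1.0)
        kern = KernelSpec(family="custom",
                          custom_fn=lambda s, t: np.where(s == t, 1.0, rho))
        ds = simulate_glnpp(ScenarioSpec("A", kern, n=50, m=m, seed=13))
        cut = estimate_cutoffs(ds)
        V2 = blup_matrix(ds, C, cut, None)
        Vg = gibbs_blup(ds, C, cut, None, n_sweeps=8000, burn=1500, seed=7)
        assert np.nanmax(np.abs(V2 - Vg)) < 0.05

    def test_truncated_mixes_exact_and_cell_predictions(self):
        X = np.array([[0.0, 1.2], [0.7, 0.0], [1.5, 2.0], [0.0, 0.4]])
        ds = make_dataset(X, kind="truncated")
        cut = estimate_cutoffs(ds)
        tr = estimate_transform(ds)
        V = blup_matrix(ds, np.eye(2), cut, tr)
        # positive observations pass through f-hat; zeros get the lower cell
        assert V[1, 0] == pytest.approx(tr(0, 0.7), abs=1e-12)
        assert V[0, 0] < 0  # conditional mean below the cutoff


class TestPredictCurve:
    def test_identity_correlation_predicts_zero(self):
        ident = lambda s, t: np.where(s == t, 1.0, 0.0)  # noqa: E731
        pred = predict_curve(np.array([[1.3, -0.2]]), [0.1, 0.5], [0.3, 0.9],
                             ident)
        np.testing.assert_allclose(pred.V, 0.0, atol=1e-12)
        np.testing.assert_allclose(pred.cond_cov, np.eye(2), atol=1e-12)

    def test_bivariate_regression_slope(self):
        rho = 0.62
        kern = lambda s, t: np.where(s == t, 1.0, rho)  # noqa: E731
        v = 1.7
        pred = predict_curve(np.array([[v]]), [0.2], [0.8], kern)
        assert pred.V[0, 0] == pytest.approx(rho * v, abs=1e-12)
        assert pred.cond_cov[0, 0] == pytest.approx(1 - rho ** 2, abs=1e-12)

    def test_binary_observed_scale_thresholding(self):
        ds = make_dataset(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
                          kind="binary")
        cut = estimate_cutoffs(ds)
        cut.cutoffs[:] = 0.5
        kern = lambda s, t: np.where(s == t, 1.0, 0.9)  # noqa: E731
        pred = predict_curve(np.array([[1.0]]), [0.0], [1.0], kern,
                             cutoffs=cut, kind="binary")
        assert pred.V[0, 0] == pytest.approx(0.9)
        assert pred.X[0, 0] == 1.0

    def test_interpolation_at_observed_points(self, rng):
        # predicting at the observed points returns the inputs exactly
        from fsgc.covariance import CovModel, SplineBasis
        U = 0.5 * (lambda A: A + A.T)(rng.normal(0, 0.3, (4, 4)))
        model = CovModel(basis=SplineBasis(d=4), U=U)
        times = np.array([0.1, 0.4, 0.8])
        V = rng.normal(size=(5, 3))
        pred = predict_curve(V, times, times, model)
        np.testing.assert_allclose(pred.V, V, atol=1e-8)


class TestLatentFpca:
    def test_rank_one_spectrum(self):
        grid = np.linspace(0, 1, 40)
        w = np.gradient(grid)
        psi = np.sin(np.pi * grid)
        psi = psi / np.sqrt(np.sum(w * psi ** 2))
        c = 2.3
        C = c * np.outer(psi, psi)
        res = latent_fpca(C, grid, var_explained=0.99)
        assert res.eigenvalues[0] == pytest.approx(c, rel=1e-10)
        assert np.abs(res.eigenvalues[1:]).max() < 1e-10
        np.testing.assert_allclose(np.abs(res.eigenfunctions[:, 0]),
                                   np.abs(psi), atol=1e-8)

    def test_identity_spectrum_is_the_quadrature_weights(self):
        # under trapezoid quadrature the identity's eigenvalues are the
        # weights themselves: interior points equal, endpoints halved
        grid = np.linspace(0, 1, 10)
        res = latent_fpca(np.eye(10), grid, var_explained=1.0)
        h = grid[1] - grid[0]
        np.testing.assert_allclose(np.sort(res.eigenvalues),
                                   np.sort(np.r_[h / 2, np.full(8, h),
                                                 h / 2]), atol=1e-12)

    def test_against_generalized_eigenproblem_oracle(self, rng):
        # independent route: nonsymmetric eigenproblem C W psi = lambda psi
        grid = np.linspace(0, 1, 50)
        A = rng.normal(size=(50, 50))
        C = A @ A.T
        d = 1 / np.sqrt(np.diag(C))
        C = C * np.outer(d, d)
        res = latent_fpca(C, grid, var_explained=1.0)
        w = res.weights
        vals = np.sort(np.real(dense_eig(C * w[None, :],
                                         right=False)))[::-1]
        np.testing.assert_allclose(res.eigenvalues, vals, atol=1e-10)

    def test_orthonormality_and_sign_convention(self, rng):
        grid = np.linspace(0, 1, 30)
        A = rng.normal(size=(30, 30))
        C = A @ A.T
        d = 1 / np.sqrt(np.diag(C))
        C = C * np.outer(d, d)
        res = latent_fpca(C, grid, var_explained=0.999)
        G = res.eigenfunctions.T @ (res.weights[:, None]
                                    * res.eigenfunctions)
        np.testing.assert_allclose(G, np.eye(res.n_components), atol=1e-10)
        assert np.all(res.eigenfunctions.sum(axis=0) >= -1e-12)


class TestScores:
    def test_score_distance_basics(self):
        assert score_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert score_distance([3.0, 4.0], [0.0, 0.0]) == 5.0
        with pytest.raises(ValueError):
            score_distance([1.0], [1.0, 2.0])

    def test_triangle_inequality(self, rng):
        for _ in range(30):
            a, b, c = rng.normal(size=(3, 4))
            assert score_distance(a, c) <= (score_distance(a, b)
                                            + score_distance(b, c) + 1e-12)

    @pytest.mark.parametrize("scenario", ["A", "B"])
    def test_first_score_recovers_truth(self, scenario):
        # latent FPC-1 scores from coarsened data correlate strongly with
        # the scores of the true latent curves
        spec = ScenarioSpec(scenario, KernelSpec(), n=1000, m=50, seed=31)
        ds, V = simulate_glnpp(spec, return_latent=True)
        from fsgc.estimators import GaussianCopulaFPCA
        kind = ds.kind.kind
        est = GaussianCopulaFPCA(kind=kind, levels=ds.kind.levels).fit(ds)
        # oracle: FPCA of the sample correlation of the true latent curves
        Ct = np.corrcoef(V.T)
        fp_t = latent_fpca(Ct, est.grid_, var_explained=0.99)
        true_scores = fpca_scores(fp_t, V)
        r = np.corrcoef(est.scores_[:, 0], true_scores[:, 0])[0, 1]
        assert abs(r) > 0.8
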