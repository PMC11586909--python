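"""Spline correlation model, Gauss–Newton NLS, BIC, PSD repair."""

import numpy as np
import pytest

from fsgc.bridging import PairBridge
from fsgc.covariance import (CovModel, SplineBasis, evaluate_cov, fit_nls,
                             gaussian_bic, inverse_fisher, repair_psd)
from fsgc.estimators import GaussianCopulaFPCA
from fsgc.kendall import TauEstimate
from fsgc.simulate import KernelSpec, ScenarioSpec, simulate_glnpp


def test_inverse_fisher_identities():
    assert inverse_fisher(0.0) == 0.0
    assert inverse_fisher(np.log(3.0)) == pytest.approx(0.5, abs=1e-15)
    assert inverse_fisher(2 * np.arctanh(0.9)) == pytest.approx(0.9,
                                                                abs=1e-15)


def _tau_from_model(model, grid, bridge):
    M = len(grid)
    j, jp = np.triu_indices(M, k=1)
    C = model.corr_matrix(grid)
    tau = np.zeros((M, M))
    tau[j, jp] = bridge.tau(C[j, jp]) if bridge.kind == "continuous" else None
    tau[jp, j] = tau[j, jp]
    return TauEstimate(grid=grid, tau=tau, counts=np.full((M, M), 1e6),
                       mask=~np.eye(M, dtype=bool), c0=5)


class TestEvaluate:
    def test_zero_coefficients_give_zero_offdiag(self):
        m = CovModel(basis=SplineBasis(d=5), U=np.zeros((5, 5)))
        assert evaluate_cov(m, 0.2, 0.7) == 0.0

    def test_unit_diagonal(self):
        m = CovModel(basis=SplineBasis(d=5), U=np.ones((5, 5)))
        assert evaluate_cov(m, 0.4, 0.4) == 1.0

    def test_symmetry(self, rng):
        U = rng.normal(size=(6, 6))
        m = CovModel(basis=SplineBasis(d=6), U=U)   # symmetrised on entry
        s, t = rng.uniform(size=(2, 100))
        np.testing.assert_allclose(evaluate_cov(m, s, t),
                                   evaluate_cov(m, t, s), atol=1e-15)


class TestFit:
    def test_noiseless_recovery_d4(self, rng):
        basis = SplineBasis(d=4)
        U0 = 0.5 * (lambda A: A + A.T)(rng.normal(0, 0.4, (4, 4)))
        truth = CovModel(basis=basis, U=U0)
        grid = np.linspace(0, 1, 30)
        br = PairBridge("continuous")
        te = _tau_from_model(truth, grid, br)
        fit = fit_nls(te, br, basis)
        assert np.abs(fit.U - U0).max() < 1e-5
        assert fit.converged

    def test_constant_surface_in_spline_span(self):
        grid = np.linspace(0, 1, 30)
        M = 30
        br = PairBridge("continuous")
        tau = np.full((M, M), br.tau(np.array([0.5]))[0])
        te = TauEstimate(grid=grid, tau=tau, counts=np.full((M, M), 1e6),
                         mask=~np.eye(M, dtype=bool), c0=5)
        fit = fit_nls(te, br, SplineBasis(d=4))
        j, jp = np.triu_indices(M, k=1)
        C = fit.corr_matrix(grid)
        assert np.abs(C[j, jp] - 0.5).max() < 1e-6

    def test_zero_tau_gives_zero_model(self):
        grid = np.linspace(0, 1, 20)
        te = TauEstimate(grid=grid, tau=np.zeros((20, 20)),
                         counts=np.full((20, 20), 1e6),
                         mask=~np.eye(20, dtype=bool), c0=5)
        fit = fit_nls(te, PairBridge("continuous"), SplineBasis(d=4))
        assert np.abs(fit.U).max() < 1e-10

    def test_descent_from_explicit_initializer(self, rng):
        # noisy tau; starting from U = 0 the fit must not increase the
        # objective
        spec = ScenarioSpec("A", KernelSpec(), n=150, m=20, seed=21)
        ds = simulate_glnpp(spec)
        from fsgc.kendall import sample_tau
        from fsgc.marginals import estimate_cutoffs
        te = sample_tau(ds)
        cuts = estimate_cutoffs(ds).cutoffs
        j, jp = te.pairs()
        br = PairBridge("binary", cuts[j], cuts[jp])
        init = np.zeros((5, 5))
        res0 = te.tau[j, jp] - br.tau(np.zeros(len(j)))
        obj0 = float(res0 @ res0)
        fit = fit_nls(te, br, SplineBasis(d=5), init=init,
                      pair_subset=(j, jp))
        assert fit.objective <= obj0

    def test_underdetermined_raises(self):
        grid = np.linspace(0, 1, 5)
        te = TauEstimate(grid=grid, tau=np.zeros((5, 5)),
                         counts=np.full((5, 5), 1e6),
                         mask=~np.eye(5, dtype=bool), c0=5)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_nls(te, PairBridge("continuous"), SplineBasis(d=5))


class TestBic:
    def test_identity_correlation_algebra(self):
        n, m, d = 40, 6, 4
        V = np.zeros((n, m))
        got = gaussian_bic(V, np.eye(m), d)
        expected = n * m * np.log(2 * np.pi) + d * (d + 1) / 2 * np.log(n)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_penalty_increases_with_dimension(self):
        V = np.random.default_rng(0).normal(size=(30, 5))
        C = np.eye(5)
        bics = [gaussian_bic(V, C, d) for d in (3, 4, 5, 6)]
        assert np.all(np.diff(bics) > 0)

    def test_modal_selection_recovers_true_dimension(self, rng):
        # continuous data whose latent correlation is an exact d0=4 spline
        # surface (projection of a smooth kernel, PSD without repair):
        # BIC should pick 4 most often over replicates
        from fsgc.covariance import _fisher, _pair_design, _unpack
        from fsgc.simulate import KernelSpec, kernel_matrix
        grid = np.linspace(0, 1, 30)
        K = 0.5 * kernel_matrix(grid, KernelSpec(scale=0.5))
        basis = SplineBasis(d=4)
        j, jp = np.triu_indices(30, k=1)
        A = _pair_design(basis, grid, j, jp)
        theta, *_ = np.linalg.lstsq(A, _fisher(K[j, jp]), rcond=None)
        truth = CovModel(basis=basis, U=_unpack(theta, 4))
        C0 = truth.corr_matrix(grid)
        assert np.linalg.eigvalsh(C0).min() > 0   # exact d0=4 surface
        root = np.linalg.cholesky(C0 + 1e-12 * np.eye(30))
        picks = []
        for rep in range(20):
            g = np.random.default_rng(1000 + rep)
            X = g.standard_normal((300, 30)) @ root.T
            est = GaussianCopulaFPCA(kind="continuous",
                                     basis_candidates=(4, 5, 6, 7))
            est.fit(X, times=grid)
            picks.append(est.n_basis_)
        vals, counts = np.unique(picks, return_counts=True)
        assert vals[np.argmax(counts)] == 4


class TestPsdRepair:
    def test_identity_is_noop(self):
        out = repair_psd(np.eye(4))
        assert not out.repaired
        np.testing.assert_array_equal(out.matrix, np.eye(4))

    def test_two_by_two_overshoot(self):
        # eigenvalues 2.2 and -0.2; clipping and rescaling pulls the
        # off-diagonal to (2.2 - eps)/(2.2 + eps) < 1
        out = repair_psd(np.array([[1.0, 1.2], [1.2, 1.0]]))
        assert out.repaired
        np.testing.assert_allclose(np.diag(out.matrix), 1.0, atol=1e-14)
        expected = (2.2 - 1e-8) / (2.2 + 1e-8)
        assert out.matrix[0, 1] == pytest.approx(expected, abs=1e-12)
        assert np.linalg.eigvalsh(out.matrix).min() >= 0

    def test_small_violation_small_change(self, rng):
        A = rng.normal(size=(8, 8))
        C = A @ A.T
        dinv = 1 / np.sqrt(np.diag(C))
        C = C * np.outer(dinv, dinv)
        w, Q = np.linalg.eigh(C)
        w[0] = -1e-6
        C_bad = (Q * w) @ Q.T
        dinv = 1 / np.sqrt(np.diag(C_bad))
        C_bad = C_bad * np.outer(dinv, dinv)
        out = repair_psd(C_bad)
        assert np.linalg.norm(out.matrix - C_bad) < 1e-4


def test_basis_partition_like_properties():
    basis = SplineBasis(d=7)
    x = np.linspace(0, 1, 101)
    B = basis.design(x)
    assert B.shape == (101, 7)
    np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)  # partition
    assert np.all(B >= 0)
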