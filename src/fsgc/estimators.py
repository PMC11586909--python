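"""Scikit-learn style estimators for latent-copula functional PCA.

:class:`GaussianCopulaFPCA` is the main estimator: it fits the latent
correlation surface of functional data observed on a continuous,
truncated, ordinal or binary scale, then exposes the latent
eigenstructure and per-subject scores.  ``transform`` maps (new) curves
to latent principal component scores, so the estimator composes with
scikit-learn pipelines and model selection.

Three reference estimators mirror the comparators of the benchmark
study: :class:`LatentPointwiseFPCA` (pointwise bridge inversion, no
spline smoothing — the multivariate variant), :class:`NonparanormalCorrelation`
(rank-based estimator that treats any input as continuous) and
:class:`NaiveFPCA` (ordinary FPCA of the observed values).

Input convention: ``X`` is an ``(n_subjects, n_times)`` array of observed
values with NaN marking unobserved cells, accompanied by ``times`` (grid
in ``[0, 1]``; defaults to equispaced), or a :class:`~fsgc.data.FunctionalDataset`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .covariance import (DEFAULT_D, SplineBasis, build_pair_bridge, fit_nls,
                         repair_psd)
from .data import FunctionalDataset, ObservationKind, to_grid_matrix
from .kendall import DEFAULT_C0, sample_tau
from .latent import blup_matrix, fpca_scores, latent_fpca, predict_curve
from .marginals import estimate_cutoffs, estimate_transform

__all__ = [
    "GaussianCopulaFPCA",
    "LatentPointwiseFPCA",
    "NonparanormalCorrelation",
    "NaiveFPCA",
]


def _as_dataset(X, times, kind: ObservationKind) -> FunctionalDataset:
    if isinstance(X, FunctionalDataset):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (subjects x times) array")
    if times is None:
        times = np.linspace(0.0, 1.0, X.shape[1])
    return FunctionalDataset.from_matrix(X, times, kind)


class _CopulaBase(BaseEstimator):
    """Shared marginal-estimation plumbing."""

    def _kind(self) -> ObservationKind:
        return ObservationKind(self.kind, getattr(self, "levels", None))

    def _marginals(self, ds: FunctionalDataset):
        cutoffs = transform = None
        if ds.kind.kind != "continuous":
            cutoffs = estimate_cutoffs(ds)
        if ds.kind.kind in ("continuous", "truncated"):
            transform = estimate_transform(ds)
        return cutoffs, transform

    def _fit_pairs(self, tau, cutoffs):
        """Unmasked pairs whose cutoffs are finite at both ends."""
        j, jp = tau.pairs()
        if cutoffs is not None:
            ok = cutoffs.finite_mask()
            keep = ok[j] & ok[jp]
            j, jp = j[keep], jp[keep]
        return j, jp


class GaussianCopulaFPCA(_CopulaBase, TransformerMixin):
    """Functional PCA through a semiparametric Gaussian copula.

    Parameters
    ----------
    kind : {"continuous", "truncated", "ordinal", "binary"}
        Observed scale of the curves.
    levels : int, optional
        Number of ordinal categories (ordinal kind only).
    n_basis : int, default 7
        Cubic B-spline basis dimension ``d`` per direction of the
        tensor-product correlation surface.
    basis_candidates : sequence of int, optional
        When given, ``d`` is chosen among these by BIC and ``n_basis``
        is ignored.
    c0 : int, default 5
        Sparse designs: grid pairs with at most ``c0`` complete
        observations are excluded from the fit.
    var_explained : float, default 0.99
        Retained latent components cover at least this fraction of
        variance.
    smooth_cutoffs : bool, default False
        Optional spline post-smoothing of the pointwise cutoff curves.

    Attributes
    ----------
    grid_ : pooled observation grid
    tau_ : sample Kendall's τ estimate
    cov_model_ : fitted spline correlation model
    correlation_ : PSD-repaired latent correlation matrix on the grid
    eigenvalues_, eigenfunctions_, explained_variance_ratio_ : latent FPCA
    latent_ : in-sample latent BLUP matrix ``V̂``
    scores_ : in-sample latent principal component scores
    """

    def __init__(self, kind="continuous", levels=None, n_basis=DEFAULT_D,
                 basis_candidates=None, c0=DEFAULT_C0, var_explained=0.99,
                 smooth_cutoffs=False):
        self.kind = kind
        self.levels = levels
        self.n_basis = n_basis
        self.basis_candidates = basis_candidates
        self.c0 = c0
        self.var_explained = var_explained
        self.smooth_cutoffs = smooth_cutoffs

    def fit(self, X, y=None, times=None):
        ds = _as_dataset(X, times, self._kind())
        self.n_features_in_ = ds.n_grid
        self.tau_ = sample_tau(ds, c0=self.c0)
        self.grid_ = self.tau_.grid
        self.cutoffs_, self.transform_ = self._marginals(ds)
        if self.cutoffs_ is not None and self.smooth_cutoffs:
            self.cutoffs_ = self.cutoffs_.smoothed()
        j, jp = self._fit_pairs(self.tau_, self.cutoffs_)
        cuts = None if self.cutoffs_ is None else self.cutoffs_.cutoffs
        bridge = build_pair_bridge(ds.kind.kind, cuts, j, jp)
        if self.basis_candidates is not None:
            from .covariance import select_d_bic

            def blup_fn(dset, C):
                return blup_matrix(dset, C, self.cutoffs_, self.transform_)

            best_d, self.bic_table_ = select_d_bic(
                ds, self.tau_, bridge, self.basis_candidates, blup_fn,
                pair_subset=(j, jp))
            self.n_basis_ = best_d
        else:
            self.n_basis_ = int(self.n_basis)
        basis = SplineBasis(d=self.n_basis_)
        self.cov_model_ = fit_nls(self.tau_, bridge, basis,
                                  pair_subset=(j, jp))
        self.correlation_ = repair_psd(
            self.cov_model_.corr_matrix(self.grid_), self.grid_)
        self.fpca_ = latent_fpca(self.correlation_,
                                 var_explained=self.var_explained)
        self.eigenvalues_ = self.fpca_.eigenvalues
        self.eigenfunctions_ = self.fpca_.eigenfunctions
        self.explained_variance_ratio_ = self.fpca_.explained_variance_ratio
        self.n_components_ = self.fpca_.n_components
        self.latent_ = blup_matrix(ds, self.correlation_, self.cutoffs_,
                                   self.transform_)
        self.scores_ = fpca_scores(self.fpca_, self.latent_)
        return self

    def transform(self, X, times=None):
        """Latent PC scores of curves under the fitted model."""
        ds = _as_dataset(X, times if times is not None else self.grid_,
                         self._kind())
        V = blup_matrix(ds, self.correlation_, self.cutoffs_, self.transform_)
        return fpca_scores(self.fpca_, V)

    def predict_curve(self, V_obs, obs_times, new_times):
        """Conditional latent/observed prediction at new time points."""
        return predict_curve(V_obs, obs_times, new_times, self.cov_model_,
                             cutoffs=self.cutoffs_, transform=self.transform_,
                             kind=self.kind)


class LatentPointwiseFPCA(_CopulaBase, TransformerMixin):
    """Unsmoothed comparator: pointwise bridge inversion of τ̂ per pair.

    Estimates the latent correlation entry-by-entry (no spline smoothing),
    repairs it to positive semidefinite, and runs latent FPCA.  Masked or
    cutoff-degenerate entries are set to zero before the PSD repair
    (flagged in ``completed_``).
    """

    def __init__(self, kind="continuous", levels=None, c0=DEFAULT_C0,
                 var_explained=0.99):
        self.kind = kind
        self.levels = levels
        self.c0 = c0
        self.var_explained = var_explained

    def fit(self, X, y=None, times=None):
        ds = _as_dataset(X, times, self._kind())
        self.n_features_in_ = ds.n_grid
        self.tau_ = sample_tau(ds, c0=self.c0)
        self.grid_ = self.tau_.grid
        self.cutoffs_, self.transform_ = self._marginals(ds)
        j, jp = self._fit_pairs(self.tau_, self.cutoffs_)
        cuts = None if self.cutoffs_ is None else self.cutoffs_.cutoffs
        bridge = build_pair_bridge(ds.kind.kind, cuts, j, jp)
        M = ds.n_grid
        raw = np.zeros((M, M))
        raw[j, jp] = bridge.inverse(self.tau_.tau[j, jp])
        raw = raw + raw.T
        np.fill_diagonal(raw, 1.0)
        self.completed_ = len(j) < M * (M - 1) // 2
        self.raw_correlation_ = raw
        self.correlation_ = repair_psd(raw, self.grid_)
        self.fpca_ = latent_fpca(self.correlation_,
                                 var_explained=self.var_explained)
        self.eigenvalues_ = self.fpca_.eigenvalues
        self.eigenfunctions_ = self.fpca_.eigenfunctions
        self.latent_ = blup_matrix(ds, self.correlation_, self.cutoffs_,
                                   self.transform_)
        self.scores_ = fpca_scores(self.fpca_, self.latent_)
        return self

    def transform(self, X, times=None):
        ds = _as_dataset(X, times if times is not None else self.grid_,
                         self._kind())
        V = blup_matrix(ds, self.correlation_, self.cutoffs_, self.transform_)
        return fpca_scores(self.fpca_, V)


class NonparanormalCorrelation(BaseEstimator):
    """Rank-based latent correlation assuming continuous margins.

    Two classical nonparanormal estimators, both deliberately misapplied
    to coarsened data as comparators:

    * ``method="scores"`` (default): Pearson correlation of the per-column
      normal scores ``Φ⁻¹(rank/(n+1))``;
    * ``method="arcsin"``: the arcsine bridge inversion
      ``Ĉ = sin(π τ̂ / 2)`` of the raw sample Kendall's τ.
    """

    def __init__(self, method="scores", c0=DEFAULT_C0):
        self.method = method
        self.c0 = c0

    def fit(self, X, y=None, times=None):
        ds = _as_dataset(X, times, ObservationKind("continuous")) \
            if not isinstance(X, FunctionalDataset) else X
        Xm, grid = to_grid_matrix(ds)
        self.n_features_in_ = Xm.shape[1]
        self.grid_ = grid
        if self.method == "scores":
            from .benchmark import normal_scores_correlation
            self.correlation_ = repair_psd(normal_scores_correlation(Xm),
                                           grid)
        elif self.method == "arcsin":
            from .kendall import sample_tau_matrix
            tau, cnt = sample_tau_matrix(Xm, c0=self.c0)
            raw = np.sin(np.pi * np.nan_to_num(tau, nan=0.0) / 2.0)
            raw[cnt <= self.c0] = 0.0
            np.fill_diagonal(raw, 1.0)
            self.correlation_ = repair_psd(raw, grid)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self


class NaiveFPCA(BaseEstimator, TransformerMixin):
    """Ordinary FPCA of the observed values (qualitative comparator).

    The sample covariance of the observed value matrix captures the
    within-curve dependence of the data on their reported scale; it is
    not an estimate of the latent correlation.
    """

    def __init__(self, var_explained=0.99):
        self.var_explained = var_explained

    def fit(self, X, y=None, times=None):
        ds = _as_dataset(X, times, ObservationKind("continuous")) \
            if not isinstance(X, FunctionalDataset) else X
        Xm, grid = to_grid_matrix(ds)
        if np.isnan(Xm).any():
            raise ValueError("naive FPCA requires a dense design")
        self.grid_ = grid
        self.n_features_in_ = Xm.shape[1]
        self.mean_ = Xm.mean(axis=0)
        Xc = Xm - self.mean_
        self.covariance_ = Xc.T @ Xc / (len(Xm) - 1)
        sd = np.sqrt(np.diag(self.covariance_))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = self.covariance_ / np.outer(sd, sd)
        self.correlation_ = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(self.correlation_, 1.0)
        self.fpca_ = latent_fpca(self.covariance_, grid,
                                 var_explained=self.var_explained)
        self.eigenvalues_ = self.fpca_.eigenvalues
        self.eigenfunctions_ = self.fpca_.eigenfunctions
        return self

    def transform(self, X, times=None):
        ds = _as_dataset(X, times if times is not None else self.grid_,
                         ObservationKind("continuous")) \
            if not isinstance(X, FunctionalDataset) else X
        Xm, _ = to_grid_matrix(ds)
        return fpca_scores(self.fpca_, Xm - self.mean_)
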