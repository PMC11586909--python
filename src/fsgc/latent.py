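"""Latent inference: BLUPs, curve prediction, latent FPCA and scores.

Given the fitted latent correlation ``ℂ̂`` and the pointwise marginal
estimates, this module predicts each subject's latent Gaussian curve
``V̂_i = E(V_i | X_i)``, extends it to unobserved time points by the
Gaussian conditional mean, and decomposes ``ℂ̂`` into latent
eigenfunctions and per-subject scores.

The conditional mean ``E(V|X)`` has no closed form for discretised data;
the default predictor proceeds in two stages: (1) pointwise
truncated-normal moments of ``V(t_j)`` given its observed cell,
(2) cross-time propagation by damped (parallel) expectation propagation —
each cell indicator is replaced by a Gaussian site factor whose moments
are matched against the cavity-tilted truncated normal, so the predictor
is exact under an identity correlation and reduces to the transformed
data for continuous observations.  An exact-mode Gibbs sampler over the
observed rectangle is provided as an oracle for small grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .covariance import LatentCorrelation
from .data import FunctionalDataset, to_grid_matrix
from .marginals import CutoffEstimates, EmpiricalTransform

__all__ = [
    "LatentPrediction",
    "FPCAResult",
    "cell_bounds",
    "blup_latent",
    "blup_matrix",
    "gibbs_blup",
    "predict_curve",
    "latent_fpca",
    "fpca_scores",
    "score_distance",
]

_RIDGE = 1e-8
_VMAX = 1.0 - 1e-12   # cap on pointwise conditional variance


@dataclass
class LatentPrediction:
    """Per-subject latent predictions at a set of time points."""

    times: np.ndarray
    V: np.ndarray                 # (n, len(times)), NaN where unavailable
    cond_cov: np.ndarray | None = None
    X: np.ndarray | None = None   # observed-scale mapping of V


@dataclass
class FPCAResult:
    """Latent eigenstructure of the correlation surface.

    Eigenfunctions are orthonormal under the trapezoid quadrature weights
    of the grid: ``Σ_j w_j ψ_k(t_j) ψ_{k'}(t_j) = δ_kk'``; signs fixed so
    ``Σ_j ψ_k(t_j) >= 0``.
    """

    grid: np.ndarray
    weights: np.ndarray
    eigenvalues: np.ndarray       # all (nonincreasing, >= 0)
    eigenfunctions: np.ndarray    # (M, K) retained components
    explained_variance_ratio: np.ndarray
    n_components: int

    @property
    def scores_basis(self) -> np.ndarray:
        """Quadrature-weighted eigenfunctions for score integrals."""
        return self.weights[:, None] * self.eigenfunctions


def cell_bounds(x: float, kind: str, cutoffs: np.ndarray):
    """Latent-cell bounds ``(lo, hi)`` implied by an observed value."""
    c = np.asarray(cutoffs, dtype=float)
    if kind == "binary":
        return (c[0], np.inf) if x > 0 else (-np.inf, c[0])
    if kind == "ordinal":
        ext = np.concatenate([[-np.inf], c, [np.inf]])
        k = int(x)
        return ext[k], ext[k + 1]
    if kind == "truncated":
        if x == 0:
            return -np.inf, c[0]
        raise ValueError("positive truncated values map through f̂, not a cell")
    raise ValueError(kind)


def _interval_moments(lo, hi):
    """Mean and variance of a standard normal conditioned on ``[lo, hi)``."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    a = norm.pdf(lo)
    b = norm.pdf(hi)
    Z = np.clip(norm.cdf(hi) - norm.cdf(lo), 1e-300, None)
    e = (a - b) / Z
    with np.errstate(invalid="ignore"):
        lo_a = np.where(np.isfinite(lo), lo * a, 0.0)
        hi_b = np.where(np.isfinite(hi), hi * b, 0.0)
    v = 1.0 + (lo_a - hi_b) / Z - e * e
    return e, np.clip(v, 0.0, _VMAX)


def _pointwise_moments(ds: FunctionalDataset, cutoffs: CutoffEstimates | None,
                       transform: EmpiricalTransform | None):
    """Per observation: conditional mean ``e`` and variance ``v`` of the
    latent value given the observed one (v = 0 where the latent value is
    pinned by the monotone transform)."""
    X, grid = to_grid_matrix(ds)
    n, M = X.shape
    e = np.full((n, M), np.nan)
    v = np.full((n, M), np.nan)
    kind = ds.kind.kind
    if kind == "continuous":
        for j in range(M):
            obs = ~np.isnan(X[:, j])
            e[obs, j] = transform(j, X[obs, j])
            v[obs, j] = 0.0
        return e, v, X
    if kind == "truncated":
        for j in range(M):
            obs = ~np.isnan(X[:, j])
            pos = obs & (X[:, j] > 0)
            zer = obs & (X[:, j] == 0)
            if np.any(pos):
                e[pos, j] = transform(j, X[pos, j])
                v[pos, j] = 0.0
            if np.any(zer):
                cut = cutoffs.cutoffs[j, 0]
                ez, vz = _interval_moments(-np.inf, cut)
                e[zer, j] = ez
                v[zer, j] = vz
        return e, v, X
    # binary / ordinal: interval moments per cell
    cext = np.concatenate([np.full((M, 1), -np.inf), cutoffs.cutoffs,
                           np.full((M, 1), np.inf)], axis=1)
    for j in range(M):
        obs = ~np.isnan(X[:, j])
        k = X[obs, j].astype(int)
        ej, vj = _interval_moments(cext[j, k], cext[j, k + 1])
        e[obs, j] = ej
        v[obs, j] = vj
    return e, v, X


def _cell_bounds_matrix(ds: FunctionalDataset, cutoffs, X, e, v):
    """Latent-cell bounds per observation (NaN moments -> unconstrained);
    pinned coordinates (v == 0) keep ``lo = hi = e``."""
    n, M = e.shape
    lo = np.full((n, M), -np.inf)
    hi = np.full((n, M), np.inf)
    kind = ds.kind.kind
    cext = None
    if kind in ("binary", "ordinal"):
        cext = np.concatenate([np.full((M, 1), -np.inf), cutoffs.cutoffs,
                               np.full((M, 1), np.inf)], axis=1)
    for j in range(M):
        obs = ~np.isnan(e[:, j])
        if kind == "truncated":
            zer = obs & (v[:, j] > 0)
            lo[zer, j] = -np.inf
            hi[zer, j] = cutoffs.cutoffs[j, 0]
        else:
            k = np.where(obs, X[:, j], 0).astype(int)
            lo[obs, j] = cext[j, k[obs]]
            hi[obs, j] = cext[j, k[obs] + 1]
    return lo, hi


def _ep_posterior_mean(Sigma, mu0, lo, hi, free, max_sweeps=100,
                       damping=0.7, tol=1e-12):
    """Damped parallel EP posterior mean of ``V ~ N(mu0, Sigma)`` given
    interval observations ``lo <= V_j <= hi`` on the ``free`` sites.

    Batched over subjects: ``mu0, lo, hi, free`` have shape ``(n, m)``
    and share the prior covariance ``Sigma``.
    """
    n, m = mu0.shape
    Sinv = np.linalg.inv(Sigma + 1e-12 * np.eye(m))
    prior_nu = mu0 @ Sinv.T
    tau_site = np.zeros((n, m))
    nu_site = np.zeros((n, m))
    mean = mu0.copy()
    Ad = np.broadcast_to(np.diag(Sigma), (n, m)).copy()
    for _ in range(max_sweeps):
        # cavity parameters from the current marginals
        var_m = np.clip(Ad, 1e-12, None)
        tau_cav = np.clip(1.0 / var_m - tau_site, 1e-10, None)
        nu_cav = mean / var_m - nu_site
        mu_cav = nu_cav / tau_cav
        sd_cav = 1.0 / np.sqrt(tau_cav)
        a = np.clip((lo - mu_cav) / sd_cav, -38, 38)
        b = np.clip((hi - mu_cav) / sd_cav, -38, 38)
        Z = np.clip(norm.cdf(b) - norm.cdf(a), 1e-300, None)
        pa, pb = norm.pdf(a), norm.pdf(b)
        r1 = (pa - pb) / Z
        mu_hat = mu_cav + sd_cav * r1
        a0 = np.where(np.isfinite(lo), a * pa, 0.0)
        b0 = np.where(np.isfinite(hi), b * pb, 0.0)
        var_hat = (1.0 / tau_cav) * np.clip(
            1.0 + (a0 - b0) / Z - r1 * r1, 1e-10, None)
        tau_new = np.clip(1.0 / var_hat - tau_cav, 0.0, 1e12)
        nu_new = mu_hat / var_hat - nu_cav
        tau_site = np.where(free, (1 - damping) * tau_site
                            + damping * tau_new, tau_site)
        nu_site = np.where(free, (1 - damping) * nu_site
                           + damping * nu_new, nu_site)
        # refresh the global Gaussian approximation
        Lam = Sinv[None, :, :] + np.einsum("ij,jk->ijk", tau_site,
                                           np.eye(m))
        A = np.linalg.inv(Lam)
        new_mean = np.einsum("ijk,ik->ij", A, prior_nu + nu_site)
        Ad = np.einsum("ijj->ij", A)
        delta = np.max(np.abs(new_mean - mean))
        mean = new_mean
        if delta < tol:
            break
    return mean


def blup_matrix(ds: FunctionalDataset, C: LatentCorrelation | np.ndarray,
                cutoffs: CutoffEstimates | None = None,
                transform: EmpiricalTransform | None = None) -> np.ndarray:
    """Latent BLUP matrix ``V̂`` of shape ``(n, M)`` (NaN where unobserved).

    Continuous data pass straight through the monotone transform.  For
    coarsened data each observed cell becomes an interval constraint on
    the latent Gaussian vector and the posterior mean is computed by
    damped parallel expectation propagation (see
    :func:`_ep_posterior_mean`); coordinates pinned by the transform
    (positive truncated values) enter through exact Gaussian
    conditioning.
    """
    Cm = C.matrix if isinstance(C, LatentCorrelation) else np.asarray(C)
    e, v, X = _pointwise_moments(ds, cutoffs, transform)
    n, M = e.shape
    Vhat = np.full((n, M), np.nan)
    obs_all = ~np.isnan(e)
    if ds.kind.kind == "continuous":
        Vhat[obs_all] = e[obs_all]
        return Vhat
    lo, hi = _cell_bounds_matrix(ds, cutoffs, X, e, v)
    # group subjects by (observed, pinned) pattern to batch EP
    pinned_all = obs_all & (v == 0.0)
    keys = np.concatenate([obs_all, pinned_all], axis=1)
    patterns = {}
    for i in range(n):
        patterns.setdefault(keys[i].tobytes(), []).append(i)
    for key, idx in patterns.items():
        flags = np.frombuffer(key, dtype=bool)
        o, p = flags[:M], flags[M:]
        if not o.any():
            continue
        f = o & ~p                  # interval-censored coordinates
        oi = np.where(o)[0]
        idx = np.asarray(idx)
        if not f.any():             # fully pinned: transform values pass
            Vhat[np.ix_(idx, oi)] = e[np.ix_(idx, oi)]
            continue
        fi = np.where(f)[0]
        pi = np.where(p)[0]
        Sig_ff = Cm[np.ix_(fi, fi)]
        if len(pi):
            Spp = Cm[np.ix_(pi, pi)] + _RIDGE * np.eye(len(pi))
            Sfp = Cm[np.ix_(fi, pi)]
            W = np.linalg.solve(Spp, Sfp.T)      # (p, f)
            Sig = Sig_ff - Sfp @ W
            mu0 = e[np.ix_(idx, pi)] @ W
            Vhat[np.ix_(idx, pi)] = e[np.ix_(idx, pi)]
        else:
            Sig = Sig_ff
            mu0 = np.zeros((len(idx), len(fi)))
        mean = _ep_posterior_mean(Sig, mu0, lo[np.ix_(idx, fi)],
                                  hi[np.ix_(idx, fi)],
                                  np.ones_like(mu0, dtype=bool))
        Vhat[np.ix_(idx, fi)] = mean
    return Vhat


def blup_latent(ds: FunctionalDataset, C: LatentCorrelation | np.ndarray,
                cutoffs: CutoffEstimates | None = None,
                transform: EmpiricalTransform | None = None) -> LatentPrediction:
    """Two-stage latent BLUPs ``E(V|X)`` for every subject (see
    :func:`blup_matrix`)."""
    grid = C.grid if isinstance(C, LatentCorrelation) else ds.pooled_grid
    V = blup_matrix(ds, C, cutoffs, transform)
    return LatentPrediction(times=np.asarray(grid), V=V)


def gibbs_blup(ds: FunctionalDataset, C: LatentCorrelation | np.ndarray,
               cutoffs: CutoffEstimates | None = None,
               transform: EmpiricalTransform | None = None,
               n_sweeps: int = 3000, burn: int = 500,
               seed: int = 0) -> np.ndarray:
    """Exact-mode BLUP oracle: Gibbs sampling of the latent Gaussian vector
    restricted to the observed rectangle (dense designs, small ``M``)."""
    Cm = C.matrix if isinstance(C, LatentCorrelation) else np.asarray(C)
    e, v, X = _pointwise_moments(ds, cutoffs, transform)
    n, M = e.shape
    rng = np.random.default_rng(seed)
    Cinv = np.linalg.inv(Cm + _RIDGE * np.eye(M))
    cond_sd = 1.0 / np.sqrt(np.diag(Cinv))
    kind = ds.kind.kind

    lo = np.full((n, M), -np.inf)
    hi = np.full((n, M), np.inf)
    fixed = v == 0.0
    for i in range(n):
        for j in range(M):
            if np.isnan(e[i, j]) or fixed[i, j]:
                continue
            if kind == "truncated":
                lo[i, j], hi[i, j] = -np.inf, cutoffs.cutoffs[j, 0]
            else:
                lo[i, j], hi[i, j] = cell_bounds(X[i, j], kind,
                                                 cutoffs.cutoffs[j])

    V = np.where(np.isnan(e), 0.0, e).copy()
    acc = np.zeros_like(V)
    kept = 0
    for sweep in range(n_sweeps):
        for j in range(M):
            mu = V @ (-Cinv[:, j] * cond_sd[j] ** 2) + V[:, j]
            free = ~fixed[:, j]
            a = (lo[:, j] - mu) / cond_sd[j]
            b = (hi[:, j] - mu) / cond_sd[j]
            u = rng.uniform(size=n)
            Fa, Fb = norm.cdf(a), norm.cdf(b)
            z = norm.ppf(Fa + u * np.clip(Fb - Fa, 1e-14, None))
            draw = mu + cond_sd[j] * np.clip(z, -38, 38)
            V[free, j] = draw[free]
        if sweep >= burn:
            acc += V
            kept += 1
    out = acc / kept
    out[np.isnan(e)] = np.nan
    return out


def predict_curve(V_obs: np.ndarray, obs_times, new_times, cov_model,
                  cutoffs: CutoffEstimates | None = None,
                  transform: EmpiricalTransform | None = None,
                  kind: str | None = None) -> LatentPrediction:
    """Gaussian conditional prediction at new time points.

    ``V̂ᴺ = ℂ_{N,O} ℂ_{O,O}⁻¹ V̂ᴼ`` with conditional covariance
    ``ℂ_{N,N} − ℂ_{N,O} ℂ_{O,O}⁻¹ ℂ_{O,N}``.  The observed-scale
    prediction pushes ``V̂ᴺ`` back through the cutoffs / transform when
    the marginal estimates are supplied (nearest-grid-point marginals).
    """
    obs_times = np.asarray(obs_times, dtype=float)
    new_times = np.asarray(new_times, dtype=float)
    V_obs = np.atleast_2d(np.asarray(V_obs, dtype=float))
    Coo = np.asarray(cov_model(obs_times[:, None], obs_times[None, :]))
    Cno = np.asarray(cov_model(new_times[:, None], obs_times[None, :]))
    Cnn = np.asarray(cov_model(new_times[:, None], new_times[None, :]))
    try:
        sol = np.linalg.solve(Coo, Cno.T)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(Coo + _RIDGE * np.eye(len(obs_times)), Cno.T)
    Vn = V_obs @ sol
    cond = Cnn - Cno @ sol
    Xn = None
    if kind is not None and kind != "latent":
        Xn = _latent_to_observed(Vn, new_times, kind, cutoffs, transform)
    return LatentPrediction(times=new_times, V=Vn, cond_cov=cond, X=Xn)


def _latent_to_observed(Vn, new_times, kind, cutoffs, transform):
    Xn = np.empty_like(Vn)
    for jn, t in enumerate(new_times):
        if kind == "continuous" or kind == "truncated":
            jref = int(np.argmin(np.abs(transform.grid - t)))
        else:
            jref = int(np.argmin(np.abs(cutoffs.grid - t)))
        if kind == "binary":
            Xn[:, jn] = (Vn[:, jn] > cutoffs.cutoffs[jref, 0]).astype(float)
        elif kind == "ordinal":
            Xn[:, jn] = np.searchsorted(cutoffs.cutoffs[jref], Vn[:, jn],
                                        side="right")
        elif kind == "truncated":
            cut = cutoffs.cutoffs[jref, 0]
            pos = Vn[:, jn] >= cut
            Xn[:, jn] = 0.0
            if np.any(pos):
                Xn[pos, jn] = transform.inverse(jref, Vn[pos, jn])
        else:
            Xn[:, jn] = transform.inverse(jref, Vn[:, jn])
    return Xn


def latent_fpca(C: LatentCorrelation | np.ndarray, grid=None,
                var_explained: float = 0.99) -> FPCAResult:
    """Eigen-decomposition of the latent correlation under trapezoid
    quadrature: solves ``∫ C(s,t) ψ_k(t) dt = λ_k ψ_k(s)`` on the grid."""
    if isinstance(C, LatentCorrelation):
        grid = C.grid
        Cm = C.matrix
    else:
        Cm = np.asarray(C)
        if grid is None:
            raise ValueError("grid required for a raw matrix")
    grid = np.asarray(grid, dtype=float)
    M = len(grid)
    w = np.zeros(M)
    if M > 1:
        dt = np.diff(grid)
        w[:-1] += dt / 2.0
        w[1:] += dt / 2.0
    else:
        w[:] = 1.0
    sw = np.sqrt(w)
    lam, Q = np.linalg.eigh(sw[:, None] * Cm * sw[None, :])
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    psi = Q[:, order] / sw[:, None]
    signs = np.where(psi.sum(axis=0) >= 0, 1.0, -1.0)
    psi = psi * signs
    ratio = lam / lam.sum() if lam.sum() > 0 else lam
    K = int(np.searchsorted(np.cumsum(ratio), var_explained) + 1)
    K = min(K, M)
    return FPCAResult(grid=grid, weights=w, eigenvalues=lam,
                      eigenfunctions=psi[:, :K],
                      explained_variance_ratio=ratio[:K], n_components=K)


def fpca_scores(fpca: FPCAResult, Vhat: np.ndarray) -> np.ndarray:
    """Quadrature scores ``ζ_ik = Σ_j w_j V̂_i(t_j) ψ_k(t_j)``.

    Missing latent values contribute zero (their conditional prior mean);
    dense designs have none.
    """
    V = np.nan_to_num(np.asarray(Vhat, dtype=float), nan=0.0)
    return V @ fpca.scores_basis


def score_distance(scores_i, scores_j) -> float:
    """Euclidean distance between two latent score vectors."""
    a = np.asarray(scores_i, dtype=float)
    b = np.asarray(scores_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    return float(np.linalg.norm(a - b))
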