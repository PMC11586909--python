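"""Latent correlation estimation by spline-bridged nonlinear least squares.

The latent correlation surface is modelled as a symmetric tensor-product
cubic B-spline pushed through the inverse Fisher link,

.. math::

    C(s, t) = g\\Big(\\sum_{k=1}^d \\sum_{l=1}^d u_{kl} B_k(s) B_l(t)\\Big),
    \\qquad g(x) = \\frac{e^x - 1}{e^x + 1} = \\tanh(x/2),

with ``U = (u_kl)`` symmetric, and fitted by Gauss–Newton on the bridged
sample Kendall's τ:

.. math::

    \\hat U = \\arg\\min_U \\sum_{(j, j')}
        \\big(\\hat\\tau_{jj'} - F(C(t_j, t_{j'}))\\big)^2 ,

the sum running over unmasked grid pairs (all ``j < j'`` for dense data;
pairs with more than ``c0`` complete observations for sparse data).  The
basis dimension ``d`` (< number of grid points) is the smoothness tuning
parameter, selectable by BIC on the latent Gaussian likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .bridging import PairBridge
from .data import FunctionalDataset
from .kendall import TauEstimate

__all__ = [
    "SplineBasis",
    "CovModel",
    "LatentCorrelation",
    "inverse_fisher",
    "evaluate_cov",
    "fit_nls",
    "select_d_bic",
    "repair_psd",
]

DEFAULT_D = 7
_PSD_EIG_FLOOR = 1e-8


def inverse_fisher(x):
    """Inverse Fisher link ``g(x) = (e^x - 1)/(e^x + 1) = tanh(x/2)``."""
    return np.tanh(np.asarray(x, dtype=float) / 2.0)


def _fisher(c):
    """Inverse of the link: ``g⁻¹(c) = 2 atanh(c)``."""
    return 2.0 * np.arctanh(np.asarray(c, dtype=float))


@dataclass(frozen=True)
class SplineBasis:
    """``d`` cubic B-spline basis functions with equispaced knots on [0,1]."""

    d: int
    degree: int = 3

    def __post_init__(self) -> None:
        if self.d < self.degree + 1:
            raise ValueError(f"need d >= {self.degree + 1} basis functions")

    @property
    def knots(self) -> np.ndarray:
        n_interior = self.d - self.degree - 1
        interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        return np.concatenate([np.zeros(self.degree + 1), interior,
                               np.ones(self.degree + 1)])

    def design(self, x) -> np.ndarray:
        """Basis evaluation matrix ``B`` of shape ``(len(x), d)``."""
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        return BSpline.design_matrix(x, self.knots, self.degree,
                                     extrapolate=False).toarray()


@dataclass
class CovModel:
    """Fitted spline correlation model ``C(s,t) = g(B(s)ᵀ U B(t))``."""

    basis: SplineBasis
    U: np.ndarray
    converged: bool = True
    objective: float = np.nan
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (self.basis.d, self.basis.d):
            raise ValueError("U must be d x d")
        self.U = 0.5 * (self.U + self.U.T)

    def __call__(self, s, t):
        return evaluate_cov(self, s, t)

    def corr_matrix(self, grid) -> np.ndarray:
        """Correlation matrix on a grid (unit diagonal by definition)."""
        B = self.basis.design(grid)
        C = inverse_fisher(B @ self.U @ B.T)
        C = 0.5 * (C + C.T)
        np.fill_diagonal(C, 1.0)
        return C


def evaluate_cov(model: CovModel, s, t):
    """Evaluate ``C(s,t)``; exactly 1 on the diagonal ``s = t``."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    scalar = s.ndim == 0 and t.ndim == 0
    s2, t2 = np.broadcast_arrays(np.atleast_1d(s), np.atleast_1d(t))
    Bs = model.basis.design(s2.ravel())
    Bt = model.basis.design(t2.ravel())
    val = inverse_fisher(np.einsum("ik,kl,il->i", Bs, model.U, Bt))
    val = np.where(s2.ravel() == t2.ravel(), 1.0, val).reshape(s2.shape)
    return float(val[0]) if scalar else val


@dataclass
class LatentCorrelation:
    """Grid-evaluated latent correlation, positive semidefinite by repair."""

    grid: np.ndarray
    matrix: np.ndarray
    repaired: bool = False
    source: str = "model"


def repair_psd(raw: np.ndarray, grid=None,
               eig_floor: float = _PSD_EIG_FLOOR) -> LatentCorrelation:
    """Clip negative eigenvalues and rescale back to unit diagonal.

    A no-op (flagged) when the input is already positive semidefinite.
    """
    A = np.asarray(raw, dtype=float)
    A = 0.5 * (A + A.T)
    w, Q = np.linalg.eigh(A)
    if w.min() >= eig_floor:
        out = A.copy()
        np.fill_diagonal(out, 1.0)
        return LatentCorrelation(grid=np.asarray(grid) if grid is not None
                                 else np.arange(len(A)), matrix=out,
                                 repaired=False)
    w = np.clip(w, eig_floor, None)
    B = (Q * w) @ Q.T
    dinv = 1.0 / np.sqrt(np.diag(B))
    out = B * dinv[:, None] * dinv[None, :]
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return LatentCorrelation(grid=np.asarray(grid) if grid is not None
                             else np.arange(len(A)), matrix=out,
                             repaired=True)


# --------------------------------------------------------------------------
# nonlinear least squares
# --------------------------------------------------------------------------

def _pair_design(basis: SplineBasis, grid, j, jp):
    """Design matrix mapping free parameters (upper triangle of U) to the
    spline score ``x_p = B(t_j)ᵀ U B(t_j')`` for each pair."""
    B = basis.design(grid)
    d = basis.d
    iu, il = np.triu_indices(d)
    # symmetric outer product per pair, flattened to the free parameters
    P = B[j][:, :, None] * B[jp][:, None, :]
    P = P + np.transpose(P, (0, 2, 1))
    A = P[:, iu, il]
    A[:, iu == il] *= 0.5
    return A


def _pack(U, d):
    iu, il = np.triu_indices(d)
    return U[iu, il]


def _unpack(theta, d):
    iu, il = np.triu_indices(d)
    U = np.zeros((d, d))
    U[iu, il] = theta
    U[il, iu] = theta
    return U


def build_pair_bridge(kind: str, cutoffs, j, jp, levels=None) -> PairBridge:
    """Per-pair bridge with the pointwise cutoff estimates frozen in."""
    if kind == "continuous":
        return PairBridge("continuous")
    cuts = np.asarray(cutoffs, dtype=float)
    return PairBridge(kind, cuts[j], cuts[jp])


def fit_nls(tau: TauEstimate, bridge: PairBridge, basis: SplineBasis,
            init: np.ndarray | None = None, max_iter: int = 200,
            tol_obj: float = 1e-10, tol_step: float = 1e-8,
            pair_subset=None) -> CovModel:
    """Gauss–Newton fit of the spline coefficient matrix ``U``.

    Parameters
    ----------
    tau : TauEstimate
        Sample Kendall's τ with its fit mask.
    bridge : PairBridge
        Per-pair bridging functions, cutoffs frozen at their estimates.
    basis : SplineBasis
    init : ndarray, optional
        Starting ``U``; default is a linear least-squares warm start from
        the pointwise bridge inversion on the ``g⁻¹`` scale.
    pair_subset : (j, jp), optional
        Explicit pair indices (defaults to the unmasked upper triangle).

    Convergence: relative objective decrease below ``tol_obj`` or step norm
    below ``tol_step``; non-convergence returns the best iterate flagged.
    """
    j, jp = tau.pairs() if pair_subset is None else pair_subset
    y = tau.tau[j, jp]
    d = basis.d
    n_par = d * (d + 1) // 2
    if len(y) < n_par:
        raise ValueError(f"underdetermined fit: {len(y)} pairs for "
                         f"{n_par} free parameters")
    A = _pair_design(basis, tau.grid, j, jp)

    if init is None:
        r0 = bridge.inverse(y)
        x0 = _fisher(np.clip(r0, -0.999, 0.999))
        theta, *_ = np.linalg.lstsq(A, x0, rcond=None)
    else:
        theta = _pack(np.asarray(init, dtype=float), d)

    def objective(th):
        res = y - bridge.tau(inverse_fisher(A @ th))
        return res, float(res @ res)

    res, obj = objective(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x = A @ theta
        g = inverse_fisher(x)
        dg = 0.5 * (1.0 - g * g)
        Fp = bridge.dtau(g)
        J = -(Fp * dg)[:, None] * A
        # Gauss–Newton step with a small Levenberg regularisation
        JtJ = J.T @ J
        JtJ[np.diag_indices_from(JtJ)] += 1e-12
        step = -np.linalg.solve(JtJ, J.T @ res)
        # step-halving line search on non-decrease
        scale = 1.0
        for _ in range(25):
            cand = theta + scale * step
            res_c, obj_c = objective(cand)
            if obj_c < obj:
                break
            scale *= 0.5
        else:
            converged = True   # no improving direction left
            break
        rel_dec = (obj - obj_c) / max(obj, 1e-300)
        theta, res, obj = cand, res_c, obj_c
        if rel_dec < tol_obj or np.linalg.norm(scale * step) < tol_step:
            converged = True
            break
    return CovModel(basis=basis, U=_unpack(theta, d), converged=converged,
                    objective=obj, n_iter=it)


# --------------------------------------------------------------------------
# BIC selection of the basis dimension
# --------------------------------------------------------------------------

def gaussian_bic(Vhat: np.ndarray, C: np.ndarray, d: int,
                 ridge: float = 1e-8) -> float:
    """BIC of latent predictions under ``V_i ~ N(0, ℂ)``:

    ``n log|ℂ| + Σ V̂ᵢᵀ ℂ⁻¹ V̂ᵢ + n m log 2π + (d(d+1)/2) log n``.
    """
    n, m = Vhat.shape
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        C = C + ridge * np.eye(m)
        sign, logdet = np.linalg.slogdet(C)
    try:
        sol = np.linalg.solve(C, Vhat.T)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(C + ridge * np.eye(m), Vhat.T)
    quad = float(np.sum(Vhat.T * sol))
    neg2ll = n * logdet + quad + n * m * np.log(2.0 * np.pi)
    return neg2ll + d * (d + 1) / 2.0 * np.log(n)


def select_d_bic(ds: FunctionalDataset, tau: TauEstimate,
                 bridge: PairBridge, candidate_ds, blup_fn,
                 pair_subset=None) -> tuple[int, dict]:
    """Fit each candidate basis dimension and pick the BIC minimiser.

    ``blup_fn(ds, C_matrix) -> V̂ (n × M)`` supplies latent predictions
    for the likelihood term (the latent module provides it); missing
    latent values contribute their prior mean zero.  Returns the best
    ``d`` and a per-candidate table of BIC values.
    """
    m = len(tau.grid)
    table = {}
    best_d, best_bic = None, np.inf
    for d in candidate_ds:
        if d >= m:
            raise ValueError(f"candidate d={d} must be < m={m}")
        model = fit_nls(tau, bridge, SplineBasis(d=d),
                        pair_subset=pair_subset)
        C = repair_psd(model.corr_matrix(tau.grid), tau.grid).matrix
        Vhat = np.nan_to_num(blup_fn(ds, C), nan=0.0)
        bic = gaussian_bic(Vhat, C, d)
        table[d] = bic
        if bic < best_bic:
            best_d, best_bic = d, bic
    return best_d, table
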