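"""Bridging functions: latent correlation ↔ population Kendall's τ.

For a pair of same-type observations generated by thresholding /
truncating / transforming a bivariate standard normal with correlation
``r``, the population Kendall's τ is a strictly increasing function
``F(r)`` that also depends on the latent cutoffs at the two time points:

* continuous–continuous:  ``F(r) = (2/π) arcsin(r)``,
* binary–binary:          ``F(r) = 2(Φ₂(Δ, Δ'; r) − Φ(Δ)Φ(Δ'))``,
* ordinal–ordinal:        the exact double sum
  ``Σ sgn(a−a′) sgn(b−b′) p_{ab}(r) p_{a′b′}(r)`` over cell probabilities
  given by bivariate-normal rectangle probabilities,
* truncated–truncated:    an exact decomposition of
  ``E sgn((X₁−X₁′)(X₂−X₂′))`` into quadrant-probability products plus
  one- and two-dimensional Gaussian integrals, evaluated by deterministic
  quadrature.

Every implementation is certified against :func:`mc_bridge_oracle`, a
Monte-Carlo estimate of the population τ with a rigorous standard error.

The bivariate normal CDF is computed from Owen's T function
(:func:`scipy.special.owens_t`), fully vectorised over points *and*
correlations, which the nonlinear least-squares fit requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from scipy.optimize import brentq


from scipy.special import ndtr as _ndtr
from scipy.special import ndtri as _ndtri
from scipy.special import owens_t as _owens_t

__all__ = [
    "BridgeSpec",
    "bvn_cdf",
    "bridge_tau",
    "bridge_dtau_dr",
    "bridge_inverse",
    "mc_bridge_oracle",
    "PairBridge",
]

# internal caps keeping the copula correlation strictly inside (-1, 1)
_RMAX = 1.0 - 1e-9         # analytic bridges (CC, BB, OO)
_RMAX_TT = 1.0 - 1e-7      # quadrature bridge (TT)
_PHI_CDF = _ndtr


def _bvn_fin(h, k, rho):
    """Bivariate normal CDF, fast path: finite args, ``|rho| < 1``."""
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    w = np.sqrt((1.0 - rho) * (1.0 + rho))
    ah = np.clip((k - rho * h) / (h * w), -1e7, 1e7)
    ak = np.clip((h - rho * k) / (k * w), -1e7, 1e7)
    ph, pk = _ndtr(h), _ndtr(k)
    val = (0.5 * (ph + pk) - _owens_t(h, ah) - _owens_t(k, ak)
           - 0.5 * (h * k < 0))
    return np.clip(val, np.clip(ph + pk - 1.0, 0.0, None), np.minimum(ph, pk))


# --------------------------------------------------------------------------
# bivariate normal CDF / PDF
# --------------------------------------------------------------------------

def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF ``P(X ≤ h, Y ≤ k)``, vectorised.

    Owen's-T formulation; ``±inf`` arguments and ``|rho| → 1`` are handled
    exactly by their limits.
    """
    h, k, rho = np.broadcast_arrays(np.asarray(h, float), np.asarray(k, float),
                                    np.asarray(rho, float))
    h = h.copy()
    k = k.copy()
    rho = np.clip(rho, -1.0, 1.0)
    out = np.empty(h.shape, dtype=float)

    sing = np.abs(rho) >= 1.0 - 1e-12
    if np.any(sing):
        hp, kp, rp = h[sing], k[sing], rho[sing]
        pos = _PHI_CDF(np.minimum(hp, kp))
        neg = np.clip(_PHI_CDF(hp) + _PHI_CDF(kp) - 1.0, 0.0, None)
        out[sing] = np.where(rp > 0, pos, neg)

    gen = ~sing
    if np.any(gen):
        hg, kg, rg = h[gen], k[gen], rho[gen]
        # infinities: P = 0 below -inf, marginal CDF above +inf
        res = np.empty(hg.shape)
        neginf = (hg == -np.inf) | (kg == -np.inf)
        posh = hg == np.inf
        posk = kg == np.inf
        fin = ~(neginf | posh | posk)
        res[neginf] = 0.0
        res[posh & ~neginf] = _PHI_CDF(kg[posh & ~neginf])
        res[posk & ~neginf & ~posh] = _PHI_CDF(hg[posk & ~neginf & ~posh])
        if np.any(fin):
            res[fin] = _bvn_fin(hg[fin], kg[fin], rg[fin])
        out[gen] = res
    return out if out.shape else float(out)


def _bvn_pdf(h, k, rho):
    """Standard bivariate normal density at ``(h, k)``."""
    w2 = (1.0 - rho) * (1.0 + rho)
    z = (h * h - 2.0 * rho * h * k + k * k) / w2
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(w2))


# --------------------------------------------------------------------------
# bridge specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BridgeSpec:
    """Same-type bridge between two time points.

    ``cutoffs_j`` / ``cutoffs_jp`` are the latent cutoff vectors at the two
    points: empty for continuous, length 1 for binary/truncated and
    ``levels - 1`` (nondecreasing) for ordinal.
    """

    kind: str
    cutoffs_j: tuple[float, ...] = ()
    cutoffs_jp: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal", "truncated"):
            raise ValueError(f"unknown kind {self.kind!r}")
        cj = tuple(float(c) for c in np.atleast_1d(self.cutoffs_j)) \
            if len(np.atleast_1d(self.cutoffs_j)) else ()
        cjp = tuple(float(c) for c in np.atleast_1d(self.cutoffs_jp)) \
            if len(np.atleast_1d(self.cutoffs_jp)) else ()
        object.__setattr__(self, "cutoffs_j", cj)
        object.__setattr__(self, "cutoffs_jp", cjp)
        if self.kind == "continuous":
            if cj or cjp:
                raise ValueError("continuous bridge takes no cutoffs")
            return
        if len(cj) != len(cjp):
            raise ValueError("cutoff vectors must have equal length")
        if self.kind in ("binary", "truncated") and len(cj) != 1:
            raise ValueError(f"{self.kind} bridge needs exactly one cutoff")
        if self.kind == "ordinal" and len(cj) < 1:
            raise ValueError("ordinal bridge needs >= 1 cutoff")
        if list(cj) != sorted(cj) or list(cjp) != sorted(cjp):
            raise ValueError("cutoff vectors must be nondecreasing")
        if self.kind != "continuous" and not (
                np.all(np.isfinite(cj)) and np.all(np.isfinite(cjp))):
            raise ValueError("bridging requires finite cutoffs")


# --------------------------------------------------------------------------
# vectorised bridges (r, cutoffs arrays -> tau array)
# --------------------------------------------------------------------------

def _tau_cc(r):
    return 2.0 / np.pi * np.arcsin(np.clip(r, -1.0, 1.0))


def _tau_bb(r, d1, d2):
    return 2.0 * (bvn_cdf(d1, d2, r) - _PHI_CDF(d1) * _PHI_CDF(d2))


def _cell_probs(r, cuts1, cuts2):
    """BVN cell probabilities over the cutoff grid.

    ``cuts1, cuts2``: (npairs, l-1) finite cutoff arrays.  Returns
    ``p`` of shape (npairs, l, l).
    """
    r = np.atleast_1d(np.asarray(r, float))
    cuts1 = np.atleast_2d(np.asarray(cuts1, float))
    cuts2 = np.atleast_2d(np.asarray(cuts2, float))
    npairs, lm1 = cuts1.shape
    ext1 = np.concatenate([np.full((npairs, 1), -np.inf), cuts1,
                           np.full((npairs, 1), np.inf)], axis=1)
    ext2 = np.concatenate([np.full((npairs, 1), -np.inf), cuts2,
                           np.full((npairs, 1), np.inf)], axis=1)
    C = bvn_cdf(ext1[:, :, None], ext2[:, None, :], r[:, None, None])
    C = np.atleast_3d(C)
    p = C[:, 1:, 1:] - C[:, :-1, 1:] - C[:, 1:, :-1] + C[:, :-1, :-1]
    return np.clip(p, 0.0, 1.0)


def _sgn_weighted(p):
    """``G[a,b] = Σ_{a'} Σ_{b'} sgn(a-a') sgn(b-b') p[a',b']`` (batched)."""

    def along(q, axis):
        c = np.cumsum(q, axis=axis)
        tot = np.take(c, [-1], axis=axis)
        below = np.concatenate(
            [np.zeros_like(np.take(c, [0], axis=axis)),
             np.take(c, range(c.shape[axis] - 1), axis=axis)], axis=axis)
        above = tot - c
        return below - above

    return along(along(p, axis=-1), axis=-2)


def _tau_oo(r, cuts1, cuts2):
    p = _cell_probs(r, cuts1, cuts2)
    return np.sum(p * _sgn_weighted(p), axis=(-2, -1))


def _dtau_oo(r, cuts1, cuts2):
    """Analytic ∂τ/∂r for the ordinal bridge via corner BVN densities."""
    r = np.atleast_1d(np.asarray(r, float))
    cuts1 = np.atleast_2d(np.asarray(cuts1, float))
    cuts2 = np.atleast_2d(np.asarray(cuts2, float))
    npairs = cuts1.shape[0]
    ext1 = np.concatenate([np.full((npairs, 1), -np.inf), cuts1,
                           np.full((npairs, 1), np.inf)], axis=1)
    ext2 = np.concatenate([np.full((npairs, 1), -np.inf), cuts2,
                           np.full((npairs, 1), np.inf)], axis=1)
    H = ext1[:, :, None]
    K = ext2[:, None, :]
    finite = np.isfinite(H) & np.isfinite(K)
    D = np.zeros(np.broadcast_shapes(H.shape, K.shape) )
    rr = np.broadcast_to(r[:, None, None], D.shape)
    D[finite] = _bvn_pdf(np.broadcast_to(H, D.shape)[finite],
                         np.broadcast_to(K, D.shape)[finite], rr[finite])
    pdot = D[:, 1:, 1:] - D[:, :-1, 1:] - D[:, 1:, :-1] + D[:, :-1, :-1]
    p = _cell_probs(r, cuts1, cuts2)
    return 2.0 * np.sum(pdot * _sgn_weighted(p), axis=(-2, -1))


def _tau_tt(r, a, b, n1d=None, n2d=None):
    """Truncated–truncated bridge by deterministic quadrature.

    ``X = V·I(V ≥ Δ)`` at both points with cutoffs ``a, b``; equivalently
    Kendall's τ of the censored pair ``(max(V₁, a), max(V₂, b))``.  The
    expectation of the sign product over two independent pairs decomposes
    into quadrant-probability products, two single integrals (one latent
    pair tied below its cutoff) and one double integral (both latent pairs
    above), the latter with bivariate-normal rectangle probabilities inside.
    All integrals use the probability transform ``u = Φ⁻¹(q)`` so the
    integrands are smooth and bounded on finite boxes.
    """
    r = np.atleast_1d(np.asarray(r, float))
    a = np.atleast_1d(np.asarray(a, float))
    b = np.atleast_1d(np.asarray(b, float))
    r, a, b = np.broadcast_arrays(r, a, b)
    r = np.clip(r, -_RMAX_TT, _RMAX_TT)
    out = np.zeros(r.shape)
    nz = r != 0.0
    if not np.any(nz):
        return out
    r, a, b = r[nz].copy(), a[nz].copy(), b[nz].copy()
    # wide integration ranges (very negative cutoffs) need more nodes
    deep = min(a.min(), b.min()) < -2.5
    if n1d is None:
        n1d = 3000 if deep else 1200
    if n2d is None:
        n2d = 48 if deep else 20
    w = np.sqrt((1.0 - r) * (1.0 + r))
    Fa, Fb = _PHI_CDF(a), _PHI_CDF(b)

    p00 = _bvn_fin(a, b, r)
    p01 = Fa - p00          # V1<=a, V2>b
    p10 = Fb - p00          # V1>a,  V2<=b
    p11 = 1.0 - Fa - Fb + p00
    quad = 2.0 * p00 * p11 - 2.0 * p01 * p10

    UB = 8.5
    hi_q = _PHI_CDF(UB)

    def one_sided(cut_lo, cut_other):
        # ∫∫_{u,v>cut_lo} φφ sgn(u−v) Φ̄((c−ru)/w) Φ((c−rv)/w), c=cut_other
        q0 = _PHI_CDF(cut_lo)
        qs = np.linspace(0.0, 1.0, n1d)
        q = q0[:, None] + (hi_q - q0)[:, None] * qs[None, :]
        u = _ndtri(np.clip(q, 1e-16, 1 - 1e-16))
        z = (cut_other[:, None] - r[:, None] * u) / w[:, None]
        alpha = _PHI_CDF(-z)          # Φ̄
        albar = 1.0 - alpha
        dq = (hi_q - q0) / (n1d - 1)
        # cumulative ∫ albar dq via trapezoid
        inc = 0.5 * (albar[:, 1:] + albar[:, :-1]) * dq[:, None]
        S = np.concatenate([np.zeros((len(r), 1)), np.cumsum(inc, axis=1)],
                           axis=1)
        Sinf = S[:, -1][:, None]
        integrand = alpha * (2.0 * S - Sinf)
        return np.sum(0.5 * (integrand[:, 1:] + integrand[:, :-1])
                      * dq[:, None], axis=1)

    t5 = one_sided(b, a)
    t7 = one_sided(a, b)

    # double integral: both latent pairs above their cutoffs
    xg, wg = np.polynomial.legendre.leggauss(n2d)
    xg = 0.5 * (xg + 1.0)   # nodes in (0, 1)
    wg = 0.5 * wg
    qa = _PHI_CDF(a)
    qu = qa[:, None] + (hi_q - qa)[:, None] * xg[None, :]      # (np, nu)
    u = _ndtri(np.clip(qu, 1e-16, 1 - 1e-16))
    wu = (hi_q - qa)[:, None] * wg[None, :]
    zlo = (b[:, None] - r[:, None] * u) / w[:, None]
    plo = _PHI_CDF(np.clip(zlo, -40, 40))
    pz = plo[:, :, None] + (hi_q - plo)[:, :, None] * xg[None, None, :]
    z = _ndtri(np.clip(pz, 1e-16, 1 - 1e-16))                  # (np, nu, nz)
    wz = (hi_q - plo)[:, :, None] * wg[None, None, :]
    v = r[:, None, None] * u[:, :, None] + w[:, None, None] * z
    r3 = np.broadcast_to(r[:, None, None], v.shape)
    u3 = np.broadcast_to(u[:, :, None], v.shape)
    a3 = np.broadcast_to(a[:, None, None], v.shape)
    G = (2.0 * _bvn_fin(u3, v, r3)
         - 2.0 * _bvn_fin(a3, v, r3)
         - (_bvn_fin(u, b[:, None], np.broadcast_to(r[:, None], u.shape))
            - p00[:, None])[:, :, None]
         - _PHI_CDF(u)[:, :, None] + Fa[:, None, None])
    t9 = 2.0 * np.sum(np.sum(G * wz, axis=2) * wu, axis=1)

    out[nz] = quad + 2.0 * t5 + 2.0 * t7 + t9
    return out


# --------------------------------------------------------------------------
# public scalar API
# --------------------------------------------------------------------------

def _tau_vec(r, spec: BridgeSpec):
    r = np.atleast_1d(np.asarray(r, float))
    r = np.clip(r, -_RMAX, _RMAX)
    if spec.kind == "continuous":
        return _tau_cc(r)
    cj = np.asarray(spec.cutoffs_j, float)
    cjp = np.asarray(spec.cutoffs_jp, float)
    if spec.kind == "binary":
        return _tau_bb(r, cj[0], cjp[0])
    if spec.kind == "ordinal":
        return _tau_oo(r, np.tile(cj, (len(r), 1)), np.tile(cjp, (len(r), 1)))
    return _tau_tt(r, cj[0], cjp[0])


def bridge_tau(r, spec: BridgeSpec) -> float | np.ndarray:
    """Population Kendall's τ ``F(r)`` for the given same-type pair.

    ``|r| >= 1`` is evaluated as the continuity limit.
    """
    out = _tau_vec(r, spec)
    return float(out[0]) if np.isscalar(r) else out


def bridge_dtau_dr(r, spec: BridgeSpec) -> float | np.ndarray:
    """Derivative ``F'(r)``; analytic except truncated (central difference)."""
    rv = np.atleast_1d(np.asarray(r, float))
    rv = np.clip(rv, -_RMAX, _RMAX)
    if spec.kind == "continuous":
        out = 2.0 / np.pi / np.sqrt((1.0 - rv) * (1.0 + rv))
    elif spec.kind == "binary":
        out = 2.0 * _bvn_pdf(spec.cutoffs_j[0], spec.cutoffs_jp[0], rv)
    elif spec.kind == "ordinal":
        cj = np.tile(np.asarray(spec.cutoffs_j, float), (len(rv), 1))
        cjp = np.tile(np.asarray(spec.cutoffs_jp, float), (len(rv), 1))
        out = _dtau_oo(rv, cj, cjp)
    else:
        h = 1e-4
        out = (_tau_vec(rv + h, spec) - _tau_vec(rv - h, spec)) / (2 * h)
    return float(out[0]) if np.isscalar(r) else out


def bridge_inverse(tau, spec: BridgeSpec, tol: float = 1e-8) -> float:
    """Unique ``r`` with ``F(r) = tau`` by bracketed root finding.

    A target outside the attainable range of ``F`` is clamped to the
    nearest endpoint (with a ``UserWarning``) — the sample τ̂ may exceed
    the population range.
    """
    rmax = _RMAX_TT if spec.kind == "truncated" else _RMAX
    if spec.kind == "continuous":
        t = float(np.clip(tau, -1.0, 1.0))
        return float(np.sin(np.pi * t / 2.0))
    lo, hi = float(_tau_vec(-rmax, spec)[0]), float(_tau_vec(rmax, spec)[0])
    if tau <= lo or tau >= hi:
        warnings.warn("tau outside the attainable bridge range; clamped",
                      UserWarning, stacklevel=2)
        return -rmax if tau <= lo else rmax
    return float(brentq(lambda r: float(_tau_vec(r, spec)[0]) - tau,
                        -rmax, rmax, xtol=tol))


class MCOracle(NamedTuple):
    tau: float
    se: float


def mc_bridge_oracle(r: float, spec: BridgeSpec, n_mc: int = 10 ** 6,
                     seed: int = 0) -> MCOracle:
    """Monte-Carlo estimate of the population τ for certification.

    Simulates ``n_mc`` independent couples of bivariate-normal pairs with
    correlation ``r``, pushes them through the observation map and averages
    the concordance signs; the returned SE is the exact finite-sample
    standard error of that mean.
    """
    if n_mc < 10 ** 4:
        raise ValueError("n_mc must be at least 1e4")
    rng = np.random.default_rng(seed)
    w = np.sqrt(max(0.0, (1.0 - r) * (1.0 + r)))

    def draw():
        z = rng.standard_normal((n_mc, 2))
        return z[:, 0], r * z[:, 0] + w * z[:, 1]

    def observe(v, cuts):
        if spec.kind == "continuous":
            return v
        if spec.kind == "binary":
            return (v > cuts[0]).astype(float)
        if spec.kind == "ordinal":
            return np.searchsorted(np.asarray(cuts), v, side="right").astype(float)
        return np.where(v >= cuts[0], v, 0.0)

    x1, x2 = draw()
    y1, y2 = draw()
    d = (np.sign(observe(x1, spec.cutoffs_j) - observe(y1, spec.cutoffs_j))
         * np.sign(observe(x2, spec.cutoffs_jp) - observe(y2, spec.cutoffs_jp)))
    return MCOracle(float(d.mean()), float(d.std(ddof=1) / np.sqrt(n_mc)))


# --------------------------------------------------------------------------
# batched per-pair bridge used by the NLS fit and the pointwise baseline
# --------------------------------------------------------------------------

@dataclass
class PairBridge:
    """Bridge evaluated simultaneously for many (cutoff_j, cutoff_j′) pairs.

    For the truncated kind the quadrature bridge is tabulated per pair with
    a Chebyshev polynomial in the arcsine-warped variable
    ``r = sin(πs/2)`` (exactly linear for the continuous bridge), which the
    iterative fit then evaluates cheaply; the other kinds are analytic.
    """

    kind: str
    cuts_j: np.ndarray | None = None    # (npairs, ncut)
    cuts_jp: np.ndarray | None = None
    cheb_deg: int = 20
    _coef: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind != "continuous":
            self.cuts_j = np.atleast_2d(np.asarray(self.cuts_j, float))
            self.cuts_jp = np.atleast_2d(np.asarray(self.cuts_jp, float))
        if self.kind == "truncated":
            s_nodes = np.cos(np.pi * (2 * np.arange(self.cheb_deg + 1) + 1)
                             / (2 * (self.cheb_deg + 1)))
            vals = np.stack([
                _tau_tt(_RMAX_TT * np.sin(np.pi * s / 2.0)
                        * np.ones(self.cuts_j.shape[0]),
                        self.cuts_j[:, 0], self.cuts_jp[:, 0])
                for s in s_nodes])
            self._coef = _cheb.chebfit(s_nodes, vals, deg=self.cheb_deg)

    @property
    def n_pairs(self) -> int:
        return 1 if self.kind == "continuous" else self.cuts_j.shape[0]

    def _s_of_r(self, r):
        x = np.clip(r / _RMAX_TT, -1.0, 1.0)
        return 2.0 / np.pi * np.arcsin(x)

    def tau(self, r: np.ndarray) -> np.ndarray:
        r = np.clip(np.asarray(r, float), -_RMAX, _RMAX)
        if self.kind == "continuous":
            return _tau_cc(r)
        if self.kind == "binary":
            return _tau_bb(r, self.cuts_j[:, 0], self.cuts_jp[:, 0])
        if self.kind == "ordinal":
            return _tau_oo(r, self.cuts_j, self.cuts_jp)
        s = self._s_of_r(r)
        return _cheb.chebval(s, self._coef, tensor=False)

    def dtau(self, r: np.ndarray) -> np.ndarray:
        r = np.clip(np.asarray(r, float), -_RMAX, _RMAX)
        if self.kind == "continuous":
            return 2.0 / np.pi / np.sqrt((1.0 - r) * (1.0 + r))
        if self.kind == "binary":
            return 2.0 * _bvn_pdf(self.cuts_j[:, 0], self.cuts_jp[:, 0], r)
        if self.kind == "ordinal":
            return _dtau_oo(r, self.cuts_j, self.cuts_jp)
        s = self._s_of_r(r)
        dF_ds = _cheb.chebval(s, _cheb.chebder(self._coef, axis=0),
                              tensor=False)
        x = np.clip(r / _RMAX_TT, -1.0 + 1e-12, 1.0 - 1e-12)
        ds_dr = 2.0 / np.pi / (np.sqrt(1.0 - x * x) * _RMAX_TT)
        return dF_ds * ds_dr

    def inverse(self, tau: np.ndarray, iters: int = 50) -> np.ndarray:
        """Vectorised monotone inversion (bisection; closed form for CC)."""
        tau = np.asarray(tau, float)
        if self.kind == "continuous":
            return np.sin(np.pi * np.clip(tau, -1.0, 1.0) / 2.0)
        rmax = _RMAX_TT if self.kind == "truncated" else _RMAX
        lo = np.full(tau.shape, -rmax)
        hi = np.full(tau.shape, rmax)
        flo = self.tau(lo)
        fhi = self.tau(hi)
        out = np.where(tau <= flo, -rmax, np.where(tau >= fhi, rmax, 0.0))
        active = (tau > flo) & (tau < fhi)
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            fm = self.tau(mid)
            go_up = fm < tau
            lo = np.where(go_up, mid, lo)
            hi = np.where(go_up, hi, mid)
        out[active] = (0.5 * (lo + hi))[active]
        return out
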