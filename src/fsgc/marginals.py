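"""Pointwise marginal estimation: cutoffs and monotone transformations.

The latent model identifies, at each time point, the cutoffs that partition
the latent standard-normal scale into the observed categories (binary /
ordinal) or the truncation point (truncated), and — for continuous and
truncated scales — the monotone transformation carrying observed values to
the latent scale.  Both are estimated pointwise by the method of moments:

* cutoffs: standard-normal quantiles of empirical category proportions;
* transformation: ``f̂_t(x) = Φ⁻¹(Ĝ_t(x))`` with the empirical CDF
  rescaled by ``1/(n_t + 1)`` so it stays strictly inside ``(0, 1)``.

No smoothness across time is enforced by default; an optional spline
post-smoother for the cutoff curves is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.stats import norm

from .data import FunctionalDataset, to_grid_matrix

__all__ = ["CutoffEstimates", "EmpiricalTransform",
           "estimate_cutoffs", "estimate_transform"]


@dataclass
class CutoffEstimates:
    """Pointwise cutoff estimates over the pooled grid.

    ``cutoffs`` has shape ``(M, n_cut)`` with ``n_cut = 1`` for binary /
    truncated and ``levels - 1`` for ordinal; rows are nondecreasing and
    may contain ``±inf`` when an empirical proportion is 0 or 1.
    """

    grid: np.ndarray
    cutoffs: np.ndarray
    kind: str

    def finite_mask(self) -> np.ndarray:
        """Per-grid-point flag: all cutoffs finite (usable for bridging)."""
        return np.all(np.isfinite(self.cutoffs), axis=1)

    def to_frame(self):
        """Long-format table with columns time, k, cutoff."""
        import pandas as pd

        M, K = self.cutoffs.shape
        return pd.DataFrame({
            "time": np.repeat(self.grid, K),
            "k": np.tile(np.arange(1, K + 1), M),
            "cutoff": self.cutoffs.ravel(),
        })

    def smoothed(self, lam: float | None = None) -> "CutoffEstimates":
        """Optional spline post-smoothing of each cutoff curve over time.

        Grid points with non-finite estimates are left out of the fit and
        filled from the smoother.  Deliberately not applied by default.
        """
        out = np.empty_like(self.cutoffs)
        for k in range(self.cutoffs.shape[1]):
            y = self.cutoffs[:, k]
            ok = np.isfinite(y)
            if ok.sum() < 4:
                out[:, k] = y
                continue
            spl = make_smoothing_spline(self.grid[ok], y[ok], lam=lam)
            out[:, k] = spl(self.grid)
        out = np.sort(out, axis=1)
        return CutoffEstimates(self.grid.copy(), out, self.kind)


def estimate_cutoffs(ds: FunctionalDataset) -> CutoffEstimates:
    """Method-of-moments cutoffs ``Δ̂(t)`` on the pooled grid.

    Binary / truncated: ``Δ̂(t) = Φ⁻¹(#{X_i(t) = 0} / n_t)``.
    Ordinal with ``l`` levels: ``Δ̂_k(t) = Φ⁻¹(#{X_i(t) ≤ k-1} / n_t)`` for
    ``k = 1, …, l-1``.  Proportions use only the subjects observed at
    ``t`` (sparse designs); grid points with no observations get NaN.
    """
    kind = ds.kind.kind
    if kind == "continuous":
        raise ValueError("cutoffs are not defined for continuous data")
    X, grid = to_grid_matrix(ds)
    obs = ~np.isnan(X)
    n_t = obs.sum(axis=0).astype(float)

    if kind in ("binary", "truncated"):
        thresholds = [0]
        n_cut = 1
    else:
        n_cut = ds.kind.levels - 1
        thresholds = list(range(n_cut))

    cuts = np.full((len(grid), n_cut), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for k, thr in enumerate(thresholds):
            cnt = np.nansum((X <= thr) & obs, axis=0)
            p = np.where(n_t > 0, cnt / np.maximum(n_t, 1), np.nan)
            cuts[:, k] = norm.ppf(p)
    return CutoffEstimates(grid=grid, cutoffs=cuts, kind=kind)


@dataclass
class EmpiricalTransform:
    """Pointwise monotone step maps ``f̂_t`` to the latent normal scale.

    For each grid point the map is built from the sorted observed sample
    (positive part only for truncated data): ``f̂_t(x) = Φ⁻¹(Ĝ_t(x))``
    with ``Ĝ_t(x) = #{X_i(t) ≤ x} / (n_t + 1)``.
    """

    grid: np.ndarray
    samples: list[np.ndarray]  # sorted positive-part sample per grid point
    n_t: np.ndarray            # CDF denominator basis (count entering Ĝ)
    n_zero: np.ndarray         # zeros at t (truncated data; counted by Ĝ)
    kind: str

    def __call__(self, j: int, x) -> np.ndarray:
        """Evaluate ``f̂_{t_j}`` at values ``x``."""
        s = self.samples[j]
        if len(s) == 0 and self.n_zero[j] == 0:
            return np.full(np.shape(x), np.nan)
        cnt = self.n_zero[j] + np.searchsorted(
            s, np.asarray(x, dtype=float), side="right")
        return norm.ppf(cnt / (self.n_t[j] + 1.0))

    def inverse(self, j: int, z) -> np.ndarray:
        """Right-continuous step inverse: smallest sample value with
        ``f̂_t(x) >= z`` (clamped to the observed support)."""
        s = self.samples[j]
        z = np.asarray(z, dtype=float)
        if len(s) == 0:
            return np.full(z.shape, np.nan)
        # f̂ at the sorted sample points (ties share the upper rank)
        fvals = self(j, s)
        idx = np.clip(np.searchsorted(fvals, z, side="left"), 0, len(s) - 1)
        return s[idx]


def estimate_transform(ds: FunctionalDataset) -> EmpiricalTransform:
    """Rescaled-empirical-CDF estimate of the monotone maps ``f̂_t``.

    Only available for continuous and truncated scales (the transformation
    is not estimable from binary or ordinal data).  For truncated data the
    map is defined on the positive part; the count ``n_t`` still includes
    the zeros so that ``Ĝ_t`` estimates the unconditional CDF.
    """
    kind = ds.kind.kind
    if kind not in ("continuous", "truncated"):
        raise ValueError("transformation is estimable only for "
                         "continuous or truncated data")
    X, grid = to_grid_matrix(ds)
    samples = []
    n_t = np.zeros(len(grid))
    n_zero = np.zeros(len(grid), dtype=int)
    for j in range(len(grid)):
        col = X[:, j]
        col = col[~np.isnan(col)]
        n_t[j] = len(col)
        if kind == "truncated":
            n_zero[j] = int(np.sum(col == 0))
            col = col[col > 0]
        samples.append(np.sort(col))
    return EmpiricalTransform(grid=grid, samples=samples, n_t=n_t,
                              n_zero=n_zero, kind=kind)
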