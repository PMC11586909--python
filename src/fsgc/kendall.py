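"""Pairwise sample Kendall's τ over the pooled grid.

For every pair of grid points :math:`(t_j, t_{j'})` the sample τ averages
the concordance signs

.. math::

    \\hat\\tau_{jj'} = \\frac{1}{N_{jj'}} \\sum_{i<i'}
        \\operatorname{sgn}\\big((X_i(t_j)-X_{i'}(t_j))
                               (X_i(t_{j'})-X_{i'}(t_{j'}))\\big)

over the :math:`N_{jj'}` subject pairs observed at both time points
(``N = n(n-1)/2`` in the dense case).  Ties contribute ``sgn(0) = 0``
(the τ-a convention); no tie correction is applied because the bridging
functions absorb ties through the cutoffs.  Pairs with too few complete
observations (``N ≤ c0``) are masked out of downstream fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FunctionalDataset, to_grid_matrix

__all__ = ["TauEstimate", "sample_tau", "sample_tau_matrix"]

DEFAULT_C0 = 5

# subject-pair chunk size for the sign outer products (memory control)
_CHUNK = 200_000


@dataclass
class TauEstimate:
    """Symmetric τ̂ matrix with pairwise-complete counts and fit mask."""

    grid: np.ndarray
    tau: np.ndarray     # (M, M), NaN where undefined
    counts: np.ndarray  # N_jj' pairwise-complete subject-pair counts
    mask: np.ndarray    # True where N_jj' > c0 (off-diagonal, upper incl.)
    c0: int

    def pairs(self):
        """Unmasked upper-triangle indices ``(j, j')`` with ``j < j'``."""
        j, jp = np.triu_indices(len(self.grid), k=1)
        keep = self.mask[j, jp]
        return j[keep], jp[keep]

    def to_frame(self) -> pd.DataFrame:
        j, jp = np.triu_indices(len(self.grid), k=1)
        return pd.DataFrame({"j": j, "j_prime": jp,
                             "tau": self.tau[j, jp], "N": self.counts[j, jp]})


def sample_tau_matrix(X: np.ndarray, c0: int = DEFAULT_C0):
    """τ̂ and pairwise counts from an ``n × M`` matrix (NaN = missing)."""
    X = np.asarray(X, dtype=float)
    n, M = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects for Kendall's tau")
    ii, jj = np.triu_indices(n, k=1)
    num = np.zeros((M, M))
    cnt = np.zeros((M, M))
    for lo in range(0, len(ii), _CHUNK):
        sl = slice(lo, lo + _CHUNK)
        D = X[ii[sl]] - X[jj[sl]]           # pairwise differences
        S = np.sign(np.nan_to_num(D, nan=0.0)).astype(np.float32)
        V = (~np.isnan(D)).astype(np.float32)
        num += (S.T @ S).astype(float)
        cnt += (V.T @ V).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    return tau, cnt


def sample_tau(ds: FunctionalDataset, c0: int = DEFAULT_C0) -> TauEstimate:
    """Sample Kendall's τ of a functional dataset over its pooled grid."""
    X, grid = to_grid_matrix(ds)
    tau, cnt = sample_tau_matrix(X, c0=c0)
    mask = cnt > c0
    np.fill_diagonal(mask, False)
    return TauEstimate(grid=grid, tau=tau, counts=cnt, mask=mask, c0=c0)
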