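"""Data model for functional observations of four scales.

A functional sample is a collection of curves :math:`X_i(t)` observed at
(possibly subject-specific) time points in :math:`[0, 1]`.  The observed
scale is one of

* ``continuous`` — unrestricted real values,
* ``truncated``  — nonnegative values with a point mass at zero,
* ``ordinal``    — integer codes ``0 … levels-1``,
* ``binary``     — ``{0, 1}`` (an ordinal scale with two levels).

Data travel in long format (``subject, time, value``) with an optional YAML
sidecar describing the scale, and are aligned on the pooled grid
:math:`t_1 < \\dots < t_M` (union of all subjects' observation times) for
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ObservationKind",
    "FunctionalDataset",
    "read_long_table",
    "write_long_table",
    "to_grid_matrix",
]

_KINDS = ("continuous", "truncated", "ordinal", "binary")

#: decimal digits used to merge float-noise duplicates on the pooled grid
GRID_DECIMALS = 12


@dataclass(frozen=True)
class ObservationKind:
    """Observed scale of a functional variable.

    Parameters
    ----------
    kind : {"continuous", "truncated", "ordinal", "binary"}
    levels : int, optional
        Number of ordinal categories ``l >= 2``.  Required for ordinal;
        binary fixes ``levels = 2``; ignored otherwise.
    """

    kind: str
    levels: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if self.kind == "binary":
            object.__setattr__(self, "levels", 2)
        elif self.kind == "ordinal":
            if self.levels is None or int(self.levels) < 2:
                raise ValueError("ordinal kind requires levels >= 2")
            object.__setattr__(self, "levels", int(self.levels))
        else:
            object.__setattr__(self, "levels", None)

    @property
    def is_discrete(self) -> bool:
        return self.kind in ("ordinal", "binary")

    def validate_values(self, values: np.ndarray) -> None:
        """Raise ``ValueError`` if any value is illegal for this scale."""
        v = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite values in data")
        if self.kind in ("binary", "ordinal"):
            levels = self.levels
            ok = (v == np.round(v)) & (v >= 0) & (v <= levels - 1)
            if not np.all(ok):
                bad = v[~ok]
                raise ValueError(
                    f"{self.kind} values must be integers in "
                    f"{{0,...,{levels - 1}}}; got e.g. {bad[:3]}"
                )
        elif self.kind == "truncated":
            if np.any(v < 0):
                raise ValueError("truncated values must be >= 0")


@dataclass
class FunctionalDataset:
    """Long-format functional data aligned on a pooled grid.

    Attributes
    ----------
    kind : ObservationKind
    subjects : ndarray of shape (n_records,)
        Subject key per record (opaque; order defines subject indexing).
    times : ndarray of shape (n_records,)
        Observation times in ``[0, 1]``.
    values : ndarray of shape (n_records,)
    """

    kind: ObservationKind
    subjects: np.ndarray
    times: np.ndarray
    values: np.ndarray
    subject_ids: np.ndarray = field(init=False)
    pooled_grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.subjects.shape == self.times.shape == self.values.shape):
            raise ValueError("subjects, times and values must be equal length")
        if np.any(self.times < -1e-12) or np.any(self.times > 1 + 1e-12):
            raise ValueError("times must lie in [0, 1]; use rescale_times=True")
        self.times = np.round(np.clip(self.times, 0.0, 1.0), GRID_DECIMALS)
        self.kind.validate_values(self.values)
        self.subject_ids = pd.unique(self.subjects)
        self.pooled_grid = np.unique(self.times)
        # duplicate (subject, time) detection
        df = pd.DataFrame({"s": self.subjects, "t": self.times})
        if df.duplicated().any():
            raise ValueError("duplicate (subject, time) pairs")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_grid(self) -> int:
        return len(self.pooled_grid)

    @property
    def counts(self) -> np.ndarray:
        """Per-subject numbers of observations ``m_i`` (subject_ids order)."""
        c = pd.Series(self.subjects).value_counts()
        return c.reindex(self.subject_ids).to_numpy()

    @property
    def is_dense(self) -> bool:
        """True iff every subject is observed at every pooled grid point."""
        return bool(np.all(self.counts == self.n_grid))

    @classmethod
    def from_matrix(cls, X, grid, kind: ObservationKind,
                    subject_ids=None) -> "FunctionalDataset":
        """Build a dataset from an ``n × M`` value matrix (NaN = missing)."""
        X = np.asarray(X, dtype=float)
        grid = np.asarray(grid, dtype=float)
        n, M = X.shape
        if grid.shape != (M,):
            raise ValueError("grid length must match matrix columns")
        if subject_ids is None:
            subject_ids = np.arange(n)
        subject_ids = np.asarray(subject_ids)
        obs = ~np.isnan(X)
        rows, cols = np.nonzero(obs)
        return cls(kind=kind, subjects=subject_ids[rows],
                   times=grid[cols], values=X[rows, cols])


def to_grid_matrix(ds: FunctionalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-grid value matrix of shape ``(n, M)`` with NaN for missing.

    Cell ``(i, j)`` holds :math:`X_i(t_j)` when subject ``i`` was observed
    at pooled grid point ``t_j``.  Rows follow ``ds.subject_ids``, columns
    the sorted pooled grid.
    """
    sub_index = pd.Index(ds.subject_ids)
    rows = sub_index.get_indexer(ds.subjects)
    cols = np.searchsorted(ds.pooled_grid, ds.times)
    X = np.full((ds.n_subjects, ds.n_grid), np.nan)
    X[rows, cols] = ds.values
    return X, ds.pooled_grid.copy()


def _rescale(times: np.ndarray) -> np.ndarray:
    lo, hi = times.min(), times.max()
    if hi == lo:
        raise ValueError("cannot rescale: all times identical")
    return (times - lo) / (hi - lo)


def read_long_table(path, kind: ObservationKind | None = None,
                    rescale_times: bool = False) -> FunctionalDataset:
    """Read a delimited long-format table (columns subject, time, value).

    If a YAML sidecar ``<path>.yaml`` exists it supplies ``kind``,
    ``levels`` and ``rescale_times`` unless overridden by arguments.
    """
    side = f"{path}.yaml"
    meta = {}
    try:
        with open(side) as fh:
            meta = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        pass
    if kind is None:
        if "kind" not in meta:
            raise ValueError("observation kind not given and no sidecar found")
        kind = ObservationKind(meta["kind"], meta.get("levels"))
    rescale_times = bool(meta.get("rescale_times", rescale_times))

    import csv
    with open(path) as fh:
        header = fh.readline()
    try:
        sep = csv.Sniffer().sniff(header, delimiters=",;\t ").delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = {"subject", "time", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    times = df["time"].to_numpy(dtype=float)
    if rescale_times:
        times = _rescale(times)
    return FunctionalDataset(kind=kind, subjects=df["subject"].to_numpy(),
                             times=times, values=df["value"].to_numpy(float))


def write_long_table(ds: FunctionalDataset, path) -> None:
    """Write long-format CSV plus a YAML metadata sidecar."""
    pd.DataFrame({"subject": ds.subjects, "time": ds.times,
                  "value": ds.values}).to_csv(path, index=False)
    meta = {"kind": ds.kind.kind}
    if ds.kind.levels is not None:
        meta["levels"] = int(ds.kind.levels)
    with open(f"{path}.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
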