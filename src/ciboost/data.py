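"""Right-censored survival data: validated container, comparable pairs, CSV I/O.

A cohort is ``n`` subjects with an observed follow-up time ``t_i > 0``, an
event indicator ``delta_i`` (1 = event observed, 0 = right-censored) and a
numeric covariate row ``x_i``.  The subjects with ``delta_i = 1`` form the
event set E; the rest are censored.

The *comparable pairs* of a cohort are the ordered pairs ``(i, j)`` with
``delta_i = 1`` and ``t_i < t_j`` (strict): subject i's event was observed
before subject j's follow-up ended, so any model prediction can be scored on
whether it orders the pair correctly.  These pairs are the denominator of
Harrell's concordance index.  Tied times are excluded (strict inequality);
a censored subject can only appear as the later member ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "ComparablePairSet",
    "SurvivalDataError",
    "read_survival_csv",
    "write_survival_csv",
    "comparable_pairs",
    "survival_target",
]


class SurvivalDataError(ValueError):
    """Raised when survival data violate the container's invariants."""


def survival_target(time, status) -> np.ndarray:
    """Pack time/status into a structured array (fields ``time``, ``status``).

    This is the ``y`` accepted by the estimators in this package, mirroring
    the convention of survival packages built on scikit-learn.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    y = np.empty(time.shape[0], dtype=[("status", "?"), ("time", "<f8")])
    y["time"] = time
    y["status"] = status.astype(bool)
    return y


def _unpack_target(y):
    """Return (time, status) float/int arrays from a structured y or a pair."""
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        if not {"time", "status"} <= names:
            raise SurvivalDataError(
                f"structured target must have fields 'time' and 'status', got {sorted(names)}"
            )
        return np.asarray(y["time"], dtype=float), np.asarray(y["status"]).astype(int)
    time, status = y
    return np.asarray(time, dtype=float), np.asarray(status).astype(int)


@dataclass(frozen=True)
class SurvivalDataset:
    """A validated right-censored survival cohort.

    Parameters
    ----------
    time : array of shape (n,)
        Observed follow-up times, strictly positive.
    status : array of shape (n,)
        Event indicators in {0, 1}; 1 means the event was observed.
    X : array of shape (n, p)
        Real-valued covariate matrix, no missing entries.
    feature_names : sequence of str, optional
        Column identifiers; defaults to ``x0..x{p-1}``.
    """

    time: np.ndarray
    status: np.ndarray
    X: np.ndarray
    feature_names: tuple = field(default=None)

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        status_raw = np.asarray(self.status)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] != time.shape[0] and X.shape[1] == time.shape[0]:
            X = X.T
        n = time.shape[0]
        if n < 2:
            raise SurvivalDataError(f"need at least 2 subjects, got {n}")
        if status_raw.shape[0] != n or X.shape[0] != n:
            raise SurvivalDataError(
                f"length mismatch: time has {n} rows, status {status_raw.shape[0]}, X {X.shape[0]}"
            )
        if not np.all(np.isfinite(time)):
            bad = int(np.flatnonzero(~np.isfinite(time))[0])
            raise SurvivalDataError(f"non-finite time at row {bad}")
        if np.any(time <= 0):
            bad = int(np.flatnonzero(time <= 0)[0])
            raise SurvivalDataError(f"time must be > 0; row {bad} has time={time[bad]}")
        status_f = np.asarray(status_raw, dtype=float)
        if not np.all(np.isin(status_f, (0.0, 1.0))):
            bad = int(np.flatnonzero(~np.isin(status_f, (0.0, 1.0)))[0])
            raise SurvivalDataError(
                f"status must be 0 or 1; row {bad} has status={status_raw[bad]}"
            )
        if not np.all(np.isfinite(X)):
            r, c = np.argwhere(~np.isfinite(X))[0]
            raise SurvivalDataError(f"missing/non-finite covariate at row {r}, column {c}")
        names = self.feature_names
        if names is None:
            names = tuple(f"x{k}" for k in range(X.shape[1]))
        else:
            names = tuple(str(c) for c in names)
            if len(names) != X.shape[1]:
                raise SurvivalDataError(
                    f"{len(names)} feature names for {X.shape[1]} covariate columns"
                )
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status_f.astype(int))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "feature_names", names)

    # -- basic accessors -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.time.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def event_mask(self) -> np.ndarray:
        return self.status == 1

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def y(self) -> np.ndarray:
        """Structured target array for use with the estimator API."""
        return survival_target(self.time, self.status)

    def subset(self, idx) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.time[idx], self.status[idx], self.X[idx], self.feature_names
        )

    def to_frame(self, time_col: str = "time", status_col: str = "status") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, status_col, self.status)
        df.insert(0, time_col, self.time)
        return df

    @classmethod
    def from_target(cls, X, y, feature_names=None) -> "SurvivalDataset":
        time, status = _unpack_target(y)
        return cls(time, status, np.asarray(X, dtype=float), feature_names)


@dataclass(frozen=True)
class ComparablePairSet:
    """The set P of validly orderable pairs of a cohort.

    ``i_idx[k], j_idx[k]`` is the k-th pair (event subject i, later subject j),
    ordered lexicographically by (i, j).  ``size == len(i_idx) == |P|``.
    """

    i_idx: np.ndarray
    j_idx: np.ndarray

    @property
    def size(self) -> int:
        return int(self.i_idx.shape[0])

    @property
    def pairs(self):
        """List of (i, j) tuples, ordered by i then j."""
        return list(zip(self.i_idx.tolist(), self.j_idx.tolist()))

    def degrees(self, n: int) -> np.ndarray:
        """Number of pairs each of the n subjects participates in."""
        return np.bincount(self.i_idx, minlength=n) + np.bincount(self.j_idx, minlength=n)


def comparable_pairs(data) -> ComparablePairSet:
    """Enumerate the validly orderable pairs of a cohort.

    ``(i, j)`` is included iff ``status_i == 1`` and ``time_i < time_j``
    (strict; tied times are not comparable).  Accepts a
    :class:`SurvivalDataset` or a ``(time, status)`` pair.
    """
    if isinstance(data, SurvivalDataset):
        time, status = data.time, data.status
    else:
        time, status = _unpack_target(data)
    mask = (status[:, None] == 1) & (time[:, None] < time[None, :])
    i_idx, j_idx = np.nonzero(mask)  # row-major => ordered by i then j
    return ComparablePairSet(i_idx, j_idx)


def read_survival_csv(path, time_col: str = "time", status_col: str = "status") -> SurvivalDataset:
    """Read a survival cohort from a headered CSV file.

    One row per subject; ``time_col`` and ``status_col`` name the follow-up
    time and event-status columns, every remaining column is a numeric
    covariate.  No missing values are accepted.
    """
    df = pd.read_csv(path)
    for col in (time_col, status_col):
        if col not in df.columns:
            raise SurvivalDataError(f"column '{col}' not found in {path}")
    cov_cols = [c for c in df.columns if c not in (time_col, status_col)]
    for c in cov_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SurvivalDataError(
                f"non-numeric or missing covariate in column '{c}', row {row}"
            )
        df[c] = coerced
    X = df[cov_cols].to_numpy(dtype=float) if cov_cols else np.empty((len(df), 0))
    return SurvivalDataset(
        df[time_col].to_numpy(dtype=float),
        df[status_col].to_numpy(),
        X,
        tuple(cov_cols),
    )


def write_survival_csv(data: SurvivalDataset, path, time_col="time", status_col="status"):
    data.to_frame(time_col, status_col).to_csv(path, index=False)
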