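"""Survival data containers, event-driven time-axis partitioning, and
expansion of subject-level records into per-interval exposures.

The piecewise-exponential model works on a fixed partition
``S = {s0 = 0 < s1 < ... < sJ}`` of the survival time axis (times are
relative to each subject's own origin).  Within interval ``j = (s_{j-1}, s_j]``
the hazard is constant, so the likelihood factorises over
(subject, interval) *exposures*: ``u_ij`` is the time subject ``i`` spends
alive within interval ``j``.

Intervals are half-open on the left: an observed time exactly equal to a
grid point ``s_j`` belongs to the interval ending at ``s_j``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "IntervalPartition",
    "ExpandedData",
    "build_partition",
    "expand",
    "covariate_row",
    "read_table",
    "read_time_varying",
]


@dataclass
class SurvivalDataset:
    """Right-censored survival data, one record per subject.

    Parameters
    ----------
    y : ndarray, shape (N,)
        Observed survival time ``y_i = min(t_i, c_i)``; strictly positive.
    d : ndarray, shape (N,)
        Event indicator: 1 = failure observed, 0 = right censored.
    Z : ndarray, shape (N, K)
        Covariate matrix (may have K = 0 columns for a pure baseline model).
    z_tv : ndarray, shape (N, J, K), optional
        Per-interval covariate values for time-varying covariates.  The
        interval dimension must match the partition used at expansion time.
    group : ndarray of int, shape (N,), optional
        Group codes ``0..G-1`` for the shared-frailty factor model.
    """

    y: np.ndarray
    d: np.ndarray
    Z: np.ndarray
    z_tv: np.ndarray | None = None
    group: np.ndarray | None = None
    covar_names: list[str] | None = None
    group_labels: list | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.d = np.asarray(self.d)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] != self.y.shape[0] and self.Z.size == 0:
            self.Z = np.empty((self.y.shape[0], 0))
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        n = self.y.shape[0]
        if np.any(~np.isfinite(self.y)) or np.any(self.y <= 0):
            bad = int(np.flatnonzero(~np.isfinite(self.y) | (self.y <= 0))[0])
            raise ValueError(f"observed time of subject {bad} is not a positive real")
        if self.d.shape != (n,) or not np.isin(self.d, [0, 1]).all():
            raise ValueError("d must be a length-N vector of 0/1 event indicators")
        self.d = self.d.astype(int)
        if self.Z.shape[0] != n:
            raise ValueError("Z must have one row per subject")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != (n,):
                raise ValueError("group must be a length-N vector")
            if self.group.dtype.kind not in "iu" or self.group_labels is None:
                labels, codes = np.unique(self.group, return_inverse=True)
                self.group_labels = list(labels)
                self.group = codes
            self.group = self.group.astype(int)
            if self.group.min() < 0 or self.group.max() >= n:
                raise ValueError("group codes must form a contiguous set 0..G-1 with G <= N")
        if self.z_tv is not None:
            self.z_tv = np.asarray(self.z_tv, dtype=float)
            if self.z_tv.ndim != 3 or self.z_tv.shape[0] != n or self.z_tv.shape[2] != self.n_covariates:
                raise ValueError("z_tv must have shape (N, J, K)")
        if self.covar_names is None:
            self.covar_names = [f"z{k + 1}" for k in range(self.n_covariates)]

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.Z.shape[1]

    @property
    def n_groups(self) -> int:
        return 0 if self.group is None else int(self.group.max()) + 1

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.y, "status": self.d})
        for k, name in enumerate(self.covar_names):
            df[name] = self.Z[:, k]
        if self.group is not None:
            labels = self.group_labels or list(range(self.n_groups))
            df["group"] = [labels[g] for g in self.group]
        return df


@dataclass(frozen=True)
class IntervalPartition:
    """A strictly increasing grid ``s0 = 0 < s1 < ... < sJ`` of cut points."""

    S: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        if self.S.ndim != 1 or self.S.shape[0] < 2:
            raise ValueError("partition needs at least the two grid points {0, sJ}")
        if self.S[0] != 0.0:
            raise ValueError("partition must start at s0 = 0")
        if np.any(np.diff(self.S) <= 0):
            raise ValueError("grid points must be strictly increasing")

    @property
    def J(self) -> int:
        return self.S.shape[0] - 1

    @property
    def durations(self) -> np.ndarray:
        """Interval lengths ``s_j - s_{j-1}``, shape (J,)."""
        return np.diff(self.S)

    def containing_interval(self, t: np.ndarray) -> np.ndarray:
        """1-based index of the interval ``(s_{j-1}, s_j]`` containing each t."""
        t = np.asarray(t, dtype=float)
        li = np.searchsorted(self.S, t, side="left")
        if np.any(t <= 0) or np.any(t > self.S[-1]):
            bad = int(np.flatnonzero((t <= 0) | (t > self.S[-1]))[0])
            raise ValueError(f"time of subject {bad} falls outside (0, sJ]")
        return li


def build_partition(
    event_times: np.ndarray, events_per_interval: int = 2, max_time: float | None = None
) -> IntervalPartition:
    """Place grid points after every ``m``-th observed event.

    Every interior interval then contains exactly ``m`` events (the last may
    contain fewer), so all intervals carry the same amount of event-based
    information.  Tied event times are collapsed to a single candidate cut
    point, but each tied event still counts toward the every-``m`` tally,
    which prevents zero-length intervals.

    Parameters
    ----------
    event_times : array-like
        Observed failure times (censored times excluded).
    events_per_interval : int
        ``m``, the number of events per interval.
    max_time : float, optional
        Largest observed time (events or censored); a final grid point at or
        beyond it is appended when the event-based cuts fall short of it.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("cannot build a partition without any observed events")
    m = int(events_per_interval)
    if m < 1:
        raise ValueError("events_per_interval must be >= 1")
    if max_time is None:
        max_time = float(event_times.max())
    if m > event_times.size:
        warnings.warn(
            "events_per_interval exceeds the number of events; "
            "falling back to the single interval (0, max_time]",
            stacklevel=2,
        )
        return IntervalPartition(np.array([0.0, float(max_time)]))
    uniq, counts = np.unique(event_times, return_counts=True)
    cum = np.cumsum(counts)
    # a cut after every m-th event, at the unique time where the tally crosses
    crossed = (cum // m) > (np.concatenate([[0], cum[:-1]]) // m)
    cuts = uniq[crossed]
    cuts = cuts[cuts > 0]
    grid = np.concatenate([[0.0], cuts])
    if grid[-1] < max_time:
        grid = np.concatenate([grid, [float(max_time)]])
    return IntervalPartition(grid)


@dataclass
class ExpandedData:
    """Subject x interval expansion of a :class:`SurvivalDataset`.

    The (subject, interval) pairs with positive exposure are stored as flat
    arrays in interval-major order; ``offsets[j-1]:offsets[j]`` slices the
    pairs of interval ``j``.  Within an interval, subjects appear in
    descending order of observed time, so the risk set of interval ``j`` is
    the first ``n_j`` entries of the fixed subject ordering — subjects are
    never physically reordered in the dataset itself.
    """

    partition: IntervalPartition
    subject: np.ndarray  # flat pair -> subject index
    interval: np.ndarray  # flat pair -> interval index (1-based)
    u: np.ndarray  # flat pair -> exposure
    event: np.ndarray  # flat pair -> failure in this interval (bool)
    offsets: np.ndarray  # (J+1,) CSR offsets into the flat arrays
    li: np.ndarray  # (N,) last interval index per subject
    nj: np.ndarray  # (J,) risk-set size per interval
    order: np.ndarray  # subjects sorted by descending y; risk set j = order[:nj[j-1]]
    risk_sets: list[np.ndarray] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.u.shape[0]

    def pairs_of_interval(self, j: int) -> slice:
        """Slice of the flat arrays belonging to interval ``j`` (1-based)."""
        return slice(int(self.offsets[j - 1]), int(self.offsets[j]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "interval": self.interval,
                "exposure": self.u,
                "event": self.event.astype(int),
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def expand(dataset: SurvivalDataset, partition: IntervalPartition) -> ExpandedData:
    """Expand subject records into per-interval exposures and risk sets.

    ``u_ij = min(y_i, s_j) - s_{j-1}`` for every interval with ``s_{j-1} < y_i``;
    the event flag is set only at ``(i, l_i)`` when ``d_i = 1``.
    """
    S = partition.S
    y = dataset.y
    if y.max() > S[-1]:
        bad = int(np.argmax(y > S[-1]))
        raise ValueError(f"subject {bad} has y={y[bad]} beyond the last grid point sJ={S[-1]}")
    if dataset.z_tv is not None and dataset.z_tv.shape[1] != partition.J:
        raise ValueError(
            f"z_tv has {dataset.z_tv.shape[1]} intervals but the partition has J={partition.J}"
        )
    li = partition.containing_interval(y)
    order = np.argsort(-y, kind="stable")
    J = partition.J
    # risk set of interval j: subjects with y > s_{j-1}
    y_sorted_desc = y[order]
    nj = np.array([int(np.sum(y_sorted_desc > S[j - 1])) for j in range(1, J + 1)])
    subject_list, interval_list, u_list, event_list = [], [], [], []
    offsets = np.zeros(J + 1, dtype=int)
    risk_sets = []
    for j in range(1, J + 1):
        idx = order[: nj[j - 1]]
        risk_sets.append(idx)
        u_j = np.minimum(y[idx], S[j]) - S[j - 1]
        ev_j = (dataset.d[idx] == 1) & (li[idx] == j)
        subject_list.append(idx)
        interval_list.append(np.full(idx.shape[0], j, dtype=int))
        u_list.append(u_j)
        event_list.append(ev_j)
        offsets[j] = offsets[j - 1] + idx.shape[0]
    return ExpandedData(
        partition=partition,
        subject=np.concatenate(subject_list),
        interval=np.concatenate(interval_list),
        u=np.concatenate(u_list),
        event=np.concatenate(event_list),
        offsets=offsets,
        li=li,
        nj=nj,
        order=order,
        risk_sets=risk_sets,
    )


def covariate_row(dataset: SurvivalDataset, i: int, j: int) -> np.ndarray:
    """Design row ``(1, z_i1, ..., z_iK)`` of subject ``i`` in interval ``j``.

    The leading intercept column carries the baseline log-hazard state.  When
    per-interval covariates are supplied the row varies with ``j``.
    """
    if i < 0 or i >= dataset.n_subjects:
        raise IndexError(f"subject index {i} out of range")
    if dataset.z_tv is not None:
        if j < 1 or j > dataset.z_tv.shape[1]:
            raise IndexError(f"interval index {j} out of range 1..{dataset.z_tv.shape[1]}")
        z = dataset.z_tv[i, j - 1]
    else:
        if j < 1:
            raise IndexError(f"interval index {j} out of range")
        z = dataset.Z[i]
    return np.concatenate([[1.0], z])


def design_rows(dataset: SurvivalDataset, expanded: ExpandedData) -> np.ndarray:
    """Design rows with intercept for every flat (subject, interval) pair."""
    n = expanded.n_pairs
    K = dataset.n_covariates
    out = np.empty((n, K + 1))
    out[:, 0] = 1.0
    if dataset.z_tv is not None:
        out[:, 1:] = dataset.z_tv[expanded.subject, expanded.interval - 1]
    else:
        out[:, 1:] = dataset.Z[expanded.subject]
    return out


def read_table(
    path,
    time: str = "time",
    status: str = "status",
    covars: list[str] | None = None,
    group: str | None = None,
    sep: str | None = None,
) -> SurvivalDataset:
    """Read a delimited table (CSV/TSV) with named columns into a dataset."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if covars is None:
        covars = [c for c in df.columns if c not in {time, status, group}]
    Z = df[covars].to_numpy(dtype=float) if covars else np.empty((len(df), 0))
    g = df[group].to_numpy() if group is not None else None
    return SurvivalDataset(
        y=df[time].to_numpy(dtype=float),
        d=df[status].to_numpy(),
        Z=Z,
        group=g,
        covar_names=list(covars),
    )


def read_time_varying(
    path,
    subject: str = "subject",
    interval: str = "interval",
    covariate: str = "covariate",
    value: str = "value",
) -> np.ndarray:
    """Read a long-format (subject, interval, covariate, value) table into
    the dense ``(N, J, K)`` array expected by :class:`SurvivalDataset`."""
    df = pd.read_csv(path)
    subs = np.sort(df[subject].unique())
    ints = np.sort(df[interval].unique())
    covs = list(pd.unique(df[covariate]))
    out = np.full((len(subs), len(ints), len(covs)), np.nan)
    s_ix = {s: a for a, s in enumerate(subs)}
    j_ix = {j: a for a, j in enumerate(ints)}
    k_ix = {k: a for a, k in enumerate(covs)}
    for row in df.itertuples(index=False):
        out[s_ix[getattr(row, subject)], j_ix[getattr(row, interval)], k_ix[getattr(row, covariate)]] = getattr(row, value)
    if np.isnan(out).any():
        raise ValueError("long-format time-varying table is missing (subject, interval, covariate) cells")
    return out
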