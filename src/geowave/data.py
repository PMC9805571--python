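"""Shared data model: event matrices and base-partition sets.

Cytometry data arrive as an events x markers matrix (one row per measured
cell) together with one or more *base partitions* -- integer label vectors
produced by external clustering tools (FlowSOM, SPADE, Phenograph, ...).
These two containers are the inputs to every downstream operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Label used by base partitions for events they did not assign
#: (e.g. noise points from density-based clusterers).
SENTINEL = -1


@dataclass(frozen=True)
class EventMatrix:
    """N events x d markers of (transformed) expression values.

    Parameters
    ----------
    values : ndarray of shape (N, d)
        Finite marker intensities; the space in which medians and
        distances live.
    marker_names : tuple of str
        Unique marker (column) names.
    event_ids : ndarray of shape (N,)
        Opaque unique identifiers; default 0-based row indices.
    """

    values: np.ndarray
    marker_names: tuple
    event_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        n, d = values.shape
        if n < 1 or d < 1:
            raise ValueError("EventMatrix requires N >= 1 events and d >= 1 markers")
        if not np.all(np.isfinite(values)):
            raise ValueError("EventMatrix values must be finite (no NaN/Inf)")
        names = tuple(str(m) for m in self.marker_names)
        if len(names) != d:
            raise ValueError(f"{len(names)} marker names for {d} columns")
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        object.__setattr__(self, "marker_names", names)
        ids = self.event_ids
        if ids is None:
            ids = np.arange(n)
        ids = np.asarray(ids)
        if ids.shape != (n,):
            raise ValueError(f"event_ids length {ids.shape} does not match N={n}")
        if len(np.unique(ids)) != n:
            raise ValueError("event_ids must be unique")
        object.__setattr__(self, "event_ids", ids)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def take(self, indices: np.ndarray) -> "EventMatrix":
        """Row-subset preserving marker names."""
        indices = np.asarray(indices)
        return EventMatrix(
            values=self.values[indices],
            marker_names=self.marker_names,
            event_ids=self.event_ids[indices],
        )


@dataclass(frozen=True)
class BasePartitionSet:
    """B integer label vectors over the same N events.

    Each vector holds cluster ids >= 0, with ``SENTINEL`` (-1) marking
    events the partition did not assign.
    """

    labels: np.ndarray  # shape (B, N), int
    partition_names: tuple

    def __post_init__(self):
        labels = np.atleast_2d(np.asarray(self.labels))
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(np.int64)
            if not np.array_equal(as_int, labels):
                raise ValueError("partition labels must be integers")
            labels = as_int
        object.__setattr__(self, "labels", labels)
        b, n = labels.shape
        if b < 2:
            raise ValueError("an ensemble needs B >= 2 base partitions")
        names = tuple(str(p) for p in self.partition_names)
        if len(names) != b:
            raise ValueError(f"{len(names)} partition names for B={b}")
        object.__setattr__(self, "partition_names", names)
        if labels.min() < SENTINEL:
            raise ValueError("labels must be >= 0 or the sentinel -1")
        for i in range(b):
            if not np.any(labels[i] != SENTINEL):
                raise ValueError(f"partition {names[i]!r} assigns no events")

    @property
    def n_partitions(self) -> int:
        return self.labels.shape[0]

    @property
    def n_events(self) -> int:
        return self.labels.shape[1]

    def take(self, indices: np.ndarray) -> "BasePartitionSet":
        return BasePartitionSet(self.labels[:, np.asarray(indices)], self.partition_names)

    def check_aligned(self, events: EventMatrix) -> None:
        if self.n_events != events.n_events:
            raise ValueError(
                f"partition length {self.n_events} does not match "
                f"event matrix with N={events.n_events}"
            )


@dataclass(frozen=True)
class PreprocessConfig:
    """Standard preprocessing knobs.

    cofactor : arcsinh divisor (5 is conventional for mass cytometry,
        150 for fluorescence flow cytometry).
    downsample_cap : keep at most this many events (None = keep all);
        300 000 is the conventional working-set ceiling.
    seed : RNG seed for down-sampling.
    """

    cofactor: float = 5.0
    downsample_cap: int | None = 300_000
    seed: int = 42

    def __post_init__(self):
        if self.cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        if self.downsample_cap is not None and self.downsample_cap < 1:
            raise ValueError("downsample_cap must be >= 1 when set")


#: Conventional arcsinh cofactors by acquisition technology.
DEFAULT_COFACTORS = {"mass": 5.0, "flow": 150.0}

#: Conventional down-sampling ceiling for large acquisitions.
DEFAULT_DOWNSAMPLE_CAP = 300_000
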