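"""Reading, writing and standard preprocessing of cytometry tables.

Event tables are read from CSV (header row of marker names) or FCS
3.0/3.1; base-partition label vectors from single-column CSV files.
Preprocessing covers the arcsinh variance-stabilising transform
(``asinh(x / cofactor)``; cofactor 5 for mass cytometry, 150 for flow)
and uniform down-sampling to a working-set cap (conventionally 300 000
events).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from ._fcs import FCSFormatError, read_fcs
from .data import (
    DEFAULT_COFACTORS,
    DEFAULT_DOWNSAMPLE_CAP,
    SENTINEL,
    BasePartitionSet,
    EventMatrix,
)

__all__ = [
    "read_events",
    "arcsinh_transform",
    "downsample",
    "read_partitions",
    "write_result",
    "FCSFormatError",
    "DEFAULT_COFACTORS",
    "DEFAULT_DOWNSAMPLE_CAP",
]


def _select_markers(df: pd.DataFrame, markers) -> pd.DataFrame:
    if markers is None:
        return df
    missing = [m for m in markers if m not in df.columns]
    if missing:
        raise KeyError(
            f"marker(s) {missing} not found; available markers: {list(df.columns)}"
        )
    return df[list(markers)]


def read_events(path: str, format: str = "csv", markers=None) -> EventMatrix:
    """Read an event-by-marker table from CSV or FCS, preserving row order.

    Parameters
    ----------
    path : file path.
    format : ``"csv"`` or ``"fcs"``.
    markers : optional list of marker names to keep (order respected).

    Event ids default to 0-based row indices.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path)
        df = _select_markers(df, markers)
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            for col in df.columns:
                bad = pd.to_numeric(df[col], errors="coerce")
                if bad.isna().any():
                    row = int(bad.isna().idxmax())
                    raise ValueError(
                        f"non-numeric value in column {col!r}, row {row}: "
                        f"{df[col].iloc[row]!r}"
                    )
            values = df.astype(float).to_numpy()
        return EventMatrix(values.astype(float), tuple(df.columns))
    if format == "fcs":
        values, names = read_fcs(path)
        df = pd.DataFrame(values, columns=names)
        df = _select_markers(df, markers)
        return EventMatrix(df.to_numpy(), tuple(df.columns))
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'fcs'")


def arcsinh_transform(events: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """Apply x -> asinh(x / cofactor) elementwise; shape and ids unchanged."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    return EventMatrix(
        np.arcsinh(events.values / cofactor),
        events.marker_names,
        events.event_ids,
    )


def downsample(
    events: EventMatrix,
    partitions: BasePartitionSet | None = None,
    cap: int = DEFAULT_DOWNSAMPLE_CAP,
    seed: int = 42,
):
    """Uniform down-sampling without replacement to at most ``cap`` events.

    Returns ``(events, partitions)`` unchanged when N <= cap; otherwise
    exactly ``cap`` events are kept, with partition vectors subset
    consistently.  Reproducible for a fixed seed.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if partitions is not None:
        partitions.check_aligned(events)
    n = events.n_events
    if n <= cap:
        return events, partitions
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=cap, replace=False))
    sub_events = events.take(keep)
    sub_parts = partitions.take(keep) if partitions is not None else None
    return sub_events, sub_parts


def _dense_encode(raw: np.ndarray) -> np.ndarray:
    """Re-encode labels to dense 0-based ints, preserving the -1 sentinel."""
    out = np.full(raw.shape, SENTINEL, dtype=np.int64)
    mask = raw != SENTINEL
    if mask.any():
        _, inv = np.unique(raw[mask], return_inverse=True)
        out[mask] = inv
    return out


def read_partitions(paths, event_ids=None) -> BasePartitionSet:
    """Read base-partition label vectors from single-column CSV files.

    Each file holds one integer label column, optionally preceded by an
    ``event_id`` column used to align rows.  Labels are re-encoded to
    dense 0-based integers per partition; -1 is preserved as the
    unassigned sentinel.
    """
    paths = list(paths)
    vectors = []
    names = []
    for path in paths:
        df = pd.read_csv(path)
        if "event_id" in df.columns:
            df = df.sort_values("event_id") if event_ids is None else df.set_index(
                "event_id"
            ).loc[np.asarray(event_ids)].reset_index()
            label_cols = [c for c in df.columns if c != "event_id"]
        else:
            label_cols = list(df.columns)
        if len(label_cols) != 1:
            raise ValueError(f"{path}: expected a single label column, got {label_cols}")
        col = df[label_cols[0]]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.isna().any() or not np.allclose(numeric, numeric.round()):
            raise ValueError(f"{path}: non-integer label in column {label_cols[0]!r}")
        vectors.append(_dense_encode(numeric.to_numpy(dtype=np.int64)))
        names.append(os.path.splitext(os.path.basename(path))[0])
    lengths = {len(v) for v in vectors}
    if len(lengths) > 1:
        raise ValueError(
            f"partition files disagree on event count: {sorted(len(v) for v in vectors)}"
        )
    return BasePartitionSet(np.vstack(vectors), tuple(names))


def write_result(result, path: str, format: str = "csv") -> None:
    """Write a consensus result as one row per event.

    Columns: ``event_id``, ``consensus_label``, ``n_candidates``,
    ``winning_score``.  ``format`` is ``"csv"`` or ``"parquet"``; the file
    reads back to an equal table.
    """
    labels = np.asarray(result.labels)
    if labels.size == 0:
        raise ValueError("refusing to write an empty result")
    df = pd.DataFrame(
        {
            "event_id": np.asarray(result.event_ids),
            "consensus_label": labels,
            "n_candidates": np.asarray(result.candidates_per_event),
            "winning_score": np.asarray(result.winning_scores),
        }
    )
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'parquet'")
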