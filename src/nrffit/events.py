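"""Stimulus event streams.

An :class:`EventStream` holds the timed stimulus events that drive a neural
response function: onset times (seconds from session start), a categorical
condition label per event, an optional parametric covariate (repetition lag
in items or seconds, or tone frequency in Hz), and an optional train id
grouping events into stimulus trains.

Events are exchanged on disk as tab-separated text with columns
``onset  condition  value  train`` (``value`` and ``train`` optional), a
BIDS-events-like dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["EventStream", "compute_lags", "read_events", "write_events"]


@dataclass(frozen=True)
class EventStream:
    """Timed stimulus events with condition labels and parametric covariates.

    Parameters
    ----------
    onsets : array of float
        Event onset times in seconds from session start; non-negative and
        non-decreasing within each condition.
    conditions : array of int
        Condition label per event (``0 .. K-1``).
    values : array of float or None
        Parametric covariate per event: repetition lag (items or seconds) or
        stimulus frequency (Hz). ``None`` for purely categorical designs.
    trains : array of int or None
        Train id per event; events in the same train share an id. ``None``
        when trains are unknown (they can be inferred from silence gaps).
    """

    onsets: np.ndarray
    conditions: np.ndarray
    values: np.ndarray | None = None
    trains: np.ndarray | None = None

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        conditions = np.asarray(self.conditions, dtype=int)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "conditions", conditions)
        if onsets.ndim != 1 or conditions.shape != onsets.shape:
            raise ValueError("onsets and conditions must be 1-d and congruent")
        if onsets.size and onsets.min() < 0:
            raise ValueError("event onsets must be non-negative")
        for name in ("values", "trains"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float if name == "values" else int)
                if arr.shape != onsets.shape:
                    raise ValueError(f"{name} must match onsets in shape")
                object.__setattr__(self, name, arr)
        # onsets must be non-decreasing within each condition
        for k in np.unique(conditions):
            ok = onsets[conditions == k]
            if np.any(np.diff(ok) < 0):
                raise ValueError(
                    f"onsets must be non-decreasing within condition {k}"
                )

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def n_conditions(self) -> int:
        return int(self.conditions.max()) + 1 if len(self) else 0

    def with_values(self, values: np.ndarray) -> "EventStream":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        d = {"onset": self.onsets, "condition": self.conditions}
        d["value"] = self.values if self.values is not None else np.nan
        if self.trains is not None:
            d["train"] = self.trains
        return pd.DataFrame(d)


def _infer_trains(onsets: np.ndarray, gap: float) -> np.ndarray:
    """Assign train ids: a new train starts when the inter-onset gap
    (across all conditions, events in onset order) exceeds ``gap`` seconds."""
    order = np.argsort(onsets, kind="stable")
    trains = np.zeros(onsets.size, dtype=int)
    tid = 0
    for prev, cur in zip(order[:-1], order[1:]):
        if onsets[cur] - onsets[prev] > gap:
            tid += 1
        trains[cur] = tid
    out = np.empty_like(trains)
    out[order] = trains
    return out


def compute_lags(events: EventStream, mode: str = "item",
                 gap: float = 4.0) -> EventStream:
    """Fill repetition-lag covariates per event.

    ``mode="item"`` sets each event's covariate to the number of preceding
    same-condition events in its train (0 for the first); ``mode="time"``
    sets it to the seconds elapsed since the first same-condition event in
    the train (0 for the first).

    When the stream has no explicit train ids, trains are inferred with a
    silence-gap rule: a gap larger than ``gap`` seconds starts a new train.
    """
    if mode not in ("item", "time"):
        raise ValueError(f"unknown lag mode {mode!r}")
    onsets = events.onsets
    if np.any(np.diff(np.sort(onsets)) < 0):  # defensive; sort can't produce this
        raise ValueError("negative inter-onset interval")
    trains = events.trains
    if trains is None:
        trains = _infer_trains(onsets, gap)
    values = np.zeros(len(events))
    for t in np.unique(trains):
        for k in np.unique(events.conditions):
            idx = np.flatnonzero((trains == t) & (events.conditions == k))
            if idx.size == 0:
                continue
            idx = idx[np.argsort(onsets[idx], kind="stable")]
            if mode == "item":
                values[idx] = np.arange(idx.size)
            else:
                values[idx] = onsets[idx] - onsets[idx[0]]
    return replace(events, values=values, trains=trains)


def read_events(path) -> EventStream:
    """Read a tab-separated events table (``onset condition value train``)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"events file must have columns {sorted(required)}")
    values = df["value"].to_numpy(float) if "value" in df else None
    if values is not None and np.all(np.isnan(values)):
        values = None
    trains = df["train"].to_numpy(int) if "train" in df else None
    return EventStream(df["onset"].to_numpy(float),
                       df["condition"].to_numpy(int), values, trains)


def write_events(events: EventStream, path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)
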