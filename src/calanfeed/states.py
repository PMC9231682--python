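"""Door-state classification and bout extraction.

A tilt sample at or above the open threshold (30 degrees by default) codes
the door as open (1); below it, closed (0).  Consecutive identical states
form bouts (runs); the closed gaps strictly between two open bouts are the
between-feeding intervals that feed the meal-criterion fit.

Runs never span a data gap (more than ``GAP_EPOCHS`` epochs between
samples): each contiguous block is encoded on its own, and closed time that
touches a block edge is censored rather than counted as an interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .sensor_io import GAP_EPOCHS, TiltSeries

EVENT_COLUMNS = ["kind", "start", "end", "duration_s", "n_samples", "block"]


@dataclass
class StateSeries:
    """Binary door state per epoch with run-length annotations.

    ``run_id`` is a non-decreasing index of maximal same-state runs (runs
    also break at data gaps); ``run_len`` counts samples of the run up to
    and including the current one.
    """

    cow_id: str
    epoch_s: float
    timestamps: pd.DatetimeIndex
    state: np.ndarray
    run_id: np.ndarray
    run_len: np.ndarray
    block: np.ndarray

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.uint8)
        if not np.isin(self.state, (0, 1)).all():
            raise DataError("state values must be 0 or 1")

    def __len__(self) -> int:
        return len(self.state)


def _annotate_runs(state: np.ndarray, block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(state)
    if n == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    new_run = np.ones(n, dtype=bool)
    new_run[1:] = (state[1:] != state[:-1]) | (block[1:] != block[:-1])
    run_id = np.cumsum(new_run) - 1
    # position within the run, 1-based
    starts = np.flatnonzero(new_run)
    run_len = np.arange(n) - np.repeat(starts, np.diff(np.append(starts, n))) + 1
    return run_id, run_len


def classify_state(series: TiltSeries, threshold_deg: float = 30.0) -> StateSeries:
    """Code each tilt sample: < threshold -> 0 (closed), >= threshold -> 1 (open).

    The boundary is inclusive on the open side.
    """
    if not 0 < threshold_deg < 180:
        raise ConfigError("threshold must lie in (0, 180) degrees")
    state = (series.tilt_deg >= threshold_deg).astype(np.uint8)
    block = series.block_ids()
    run_id, run_len = _annotate_runs(state, block)
    return StateSeries(
        cow_id=series.cow_id,
        epoch_s=series.epoch_s,
        timestamps=series.timestamps,
        state=state,
        run_id=run_id,
        run_len=run_len,
        block=block,
    )


def smooth_mode(states: StateSeries, k: int = 5) -> StateSeries:
    """Replace each sample by the mode of a centered (2k+1)-sample window.

    The window spans the k previous samples, the sample itself and the k
    following samples; at the series edges the available window is used.
    A tie (possible only in a truncated edge window) keeps the raw value.
    """
    if k < 1:
        raise ConfigError("window half-width k must be >= 1")
    s = states.state.astype(np.int64)
    n = len(s)
    if n == 0:
        return states
    csum = np.concatenate([[0], np.cumsum(s)])
    lo = np.maximum(np.arange(n) - k, 0)
    hi = np.minimum(np.arange(n) + k + 1, n)
    ones = csum[hi] - csum[lo]
    width = hi - lo
    smoothed = np.where(2 * ones > width, 1, np.where(2 * ones < width, 0, s))
    smoothed = smoothed.astype(np.uint8)
    run_id, run_len = _annotate_runs(smoothed, states.block)
    return StateSeries(
        cow_id=states.cow_id,
        epoch_s=states.epoch_s,
        timestamps=states.timestamps,
        state=smoothed,
        run_id=run_id,
        run_len=run_len,
        block=states.block,
    )


def run_length_encode(states: StateSeries) -> pd.DataFrame:
    """Collapse a state series into an event table of alternating bouts.

    Each row is one maximal run: kind (open/closed), start timestamp, end
    (start + n_samples * epoch, exclusive), duration in seconds, sample
    count and the contiguous-block index.  Decoding the table reproduces
    the input series exactly (see :func:`decode_events`).
    """
    if len(states) == 0:
        raise DataError("cannot encode an empty state series")
    n = len(states)
    boundaries = np.flatnonzero(
        np.concatenate([[True], np.diff(states.run_id) != 0])
    )
    counts = np.diff(np.append(boundaries, n))
    starts = states.timestamps[boundaries]
    kinds = np.where(states.state[boundaries] == 1, "open", "closed")
    dur = counts * states.epoch_s
    return pd.DataFrame(
        {
            "kind": kinds,
            "start": starts,
            "end": starts + pd.to_timedelta(dur, unit="s"),
            "duration_s": dur.astype(float),
            "n_samples": counts.astype(int),
            "block": states.block[boundaries].astype(int),
        }
    )


def decode_events(events: pd.DataFrame, epoch_s: float, cow_id: str = "decoded") -> StateSeries:
    """Expand an event table back into a per-epoch state series (RLE inverse)."""
    if len(events) == 0:
        raise DataError("cannot decode an empty event table")
    counts = events["n_samples"].to_numpy(int)
    state = np.repeat((events["kind"] == "open").to_numpy(), counts).astype(np.uint8)
    ts_parts = [
        pd.date_range(start=row.start, periods=row.n_samples, freq=pd.Timedelta(seconds=epoch_s))
        for row in events.itertuples()
    ]
    ts = ts_parts[0]
    for part in ts_parts[1:]:
        ts = ts.append(part)
    block = np.repeat(events["block"].to_numpy(int), counts)
    run_id, run_len = _annotate_runs(state, block)
    return StateSeries(
        cow_id=cow_id,
        epoch_s=epoch_s,
        timestamps=ts,
        state=state,
        run_id=run_id,
        run_len=run_len,
        block=block,
    )


def extract_intervals(events: pd.DataFrame) -> pd.DataFrame:
    """Between-feeding intervals: closed bouts flanked by open bouts.

    Closed time at the start or end of a block (no bounding feeding event —
    e.g. the lockout period around feed delivery) is censored, not an
    interval.  Returns a frame with start, end and duration_s per interval.
    """
    rows = []
    for _, blk in events.groupby("block", sort=True):
        kinds = blk["kind"].to_numpy()
        for i in range(1, len(blk) - 1):
            if kinds[i] == "closed" and kinds[i - 1] == "open" and kinds[i + 1] == "open":
                rows.append(blk.iloc[i])
    if not rows:
        return pd.DataFrame(columns=["start", "end", "duration_s"])
    out = pd.DataFrame(rows)[["start", "end", "duration_s"]].reset_index(drop=True)
    return out
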