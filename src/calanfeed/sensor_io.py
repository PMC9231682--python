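"""Reading tilt-logger exports and turning raw acceleration into tilt angle.

The loggers record static acceleration on up to three axes at a fixed epoch
(30 s by default).  For a gravity-referenced axis the tilt angle follows

    tilt = 180 degrees - arccos(a)

where ``a`` is the per-axis acceleration in units of g, so that a = -1 maps
to 0 degrees (hanging straight down, door closed), a = 0 to 90 degrees and
a = +1 to 180 degrees.  Records are segmented into experimental days at a
configurable local clock boundary (05:00 by default, the daily feed-bunk
lockout), and a sag QC report counts closed-door samples that have drifted
above 0 degrees but below the open threshold.

Export dialects vary between vendor software versions, so column names are
supplied through a small column map rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import time as dtime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

#: Default logger-export column layout ("Date Time, X accel, Y accel, Z accel").
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "timestamp": "Date Time",
    "ax": "X accel",
    "ay": "Y accel",
    "az": "Z accel",
}

#: A data gap is declared when successive timestamps are more than this many
#: epochs apart.  Gaps are flagged, never interpolated.
GAP_EPOCHS = 2


@dataclass
class AccelSeries:
    """Timestamped per-axis acceleration in g at a fixed epoch."""

    cow_id: str
    epoch_s: float
    timestamps: pd.DatetimeIndex
    accel: pd.DataFrame  # columns subset of {"ax", "ay", "az"}

    def __post_init__(self) -> None:
        _check_monotone(self.timestamps)
        if not np.isfinite(self.accel.to_numpy(float)).all():
            raise DataError("non-finite acceleration value in series")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class TiltSeries:
    """Tilt angle (degrees, in [0, 180]) of one sensor axis over time.

    ``n_clipped`` counts acceleration values that were clipped to [-1, 1]
    before the arccos (sensor noise can push |a| slightly past 1 g).
    """

    cow_id: str
    epoch_s: float
    timestamps: pd.DatetimeIndex
    tilt_deg: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.tilt_deg = np.asarray(self.tilt_deg, dtype=float)
        _check_monotone(self.timestamps)
        if len(self.tilt_deg) != len(self.timestamps):
            raise DataError("tilt and timestamp lengths differ")
        if len(self.tilt_deg) and (
            np.nanmin(self.tilt_deg) < 0 or np.nanmax(self.tilt_deg) > 180
        ):
            raise DataError("tilt angle outside [0, 180] degrees")

    def __len__(self) -> int:
        return len(self.timestamps)

    def gap_starts(self) -> np.ndarray:
        """Indices i such that the step from sample i-1 to i exceeds the
        gap threshold (``GAP_EPOCHS`` epochs).  Index 0 is never a gap."""
        if len(self) < 2:
            return np.array([], dtype=int)
        dt = np.diff(self.timestamps.asi8) / 1e9
        return np.flatnonzero(dt > GAP_EPOCHS * self.epoch_s) + 1

    def block_ids(self) -> np.ndarray:
        """Contiguous-block index per sample; a new block starts at each gap."""
        blocks = np.zeros(len(self), dtype=int)
        blocks[self.gap_starts()] = 1
        return np.cumsum(blocks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cow_id": self.cow_id,
                "timestamp": self.timestamps,
                "tilt_deg": self.tilt_deg,
            }
        )


@dataclass
class DaySegment:
    """One experimental day (boundary-to-boundary slice) of a tilt record."""

    cow_id: str
    day_index: int
    start: pd.Timestamp  # nominal boundary, not first sample
    end: pd.Timestamp
    series: TiltSeries
    is_partial: bool = False


@dataclass
class QCReport:
    """Sag quality-control summary: closed-door samples drifted above 0."""

    n_total: int
    n_sag: int
    sag_fraction: float


def _check_monotone(ts: pd.DatetimeIndex) -> None:
    if len(ts) < 2:
        return
    d = np.diff(ts.asi8)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        i = int(bad[0]) + 1
        if d[bad[0]] == 0:
            raise DataError(f"duplicate timestamp at row {i}: {ts[i]}")
        raise DataError(f"non-monotone timestamp at row {i}: {ts[i]} <= {ts[i - 1]}")


def _infer_epoch(ts: pd.DatetimeIndex) -> float:
    if len(ts) < 2:
        raise DataError("cannot infer epoch from fewer than 2 samples")
    return float(np.median(np.diff(ts.asi8)) / 1e9)


def parse_logger_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    cow_id: str = "unknown",
    epoch_s: float | None = None,
    delimiter: str = ",",
):
    """Read a logger export CSV into an :class:`AccelSeries` or :class:`TiltSeries`.

    The column map names the timestamp column plus either per-axis
    acceleration columns (``ax``/``ay``/``az``, any subset) or a
    precomputed-tilt column (``tilt``).  Which one is present decides the
    return type; units are thereby recorded (g vs degrees).

    Raises
    ------
    FormatError
        A mapped column is absent from the file.
    DataError
        Timestamps are unparseable, duplicated or decreasing (the message
        names the first offending row).
    """
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    df = pd.read_csv(path, sep=delimiter)
    ts_col = cmap.get("timestamp", "timestamp")
    for key, col in [("timestamp", ts_col)] + [
        (k, v) for k, v in cmap.items() if k != "timestamp"
    ]:
        if col not in df.columns:
            raise FormatError(f"column {col!r} (mapped as {key!r}) not found in {path}")
    try:
        ts = pd.DatetimeIndex(pd.to_datetime(df[ts_col]))
    except (ValueError, TypeError) as exc:
        raise DataError(f"unparseable timestamps in {path}: {exc}") from None
    _check_monotone(ts)
    eps = epoch_s if epoch_s is not None else _infer_epoch(ts)

    if "tilt" in cmap:
        return TiltSeries(
            cow_id=cow_id,
            epoch_s=eps,
            timestamps=ts,
            tilt_deg=df[cmap["tilt"]].to_numpy(float),
        )
    axes = {k: cmap[k] for k in ("ax", "ay", "az") if k in cmap}
    if not axes:
        raise ConfigError("column_map must name a 'tilt' column or accel axes")
    accel = pd.DataFrame({k: df[v].to_numpy(float) for k, v in axes.items()})
    return AccelSeries(cow_id=cow_id, epoch_s=eps, timestamps=ts, accel=accel)


def compute_tilt(samples: AccelSeries, axis: str = "z", clip_tol: float = 0.05) -> TiltSeries:
    """Convert one acceleration axis to tilt: ``180 - degrees(arccos(a))``.

    Values of |a| up to ``1 + clip_tol`` are clipped to the unit interval
    before the arccos (the count is kept on the result); anything larger
    indicates mis-scaled units and raises :class:`DataError`.
    """
    key = "a" + axis.lower()
    if key not in samples.accel.columns:
        raise ConfigError(f"axis {axis!r} not present in series (has {list(samples.accel.columns)})")
    a = samples.accel[key].to_numpy(float)
    over = np.abs(a) > 1.0 + clip_tol
    if over.any():
        i = int(np.flatnonzero(over)[0])
        raise DataError(
            f"|acceleration| = {abs(a[i]):.3f} g at row {i} exceeds 1 + {clip_tol}; "
            "values look mis-scaled (not in units of g)"
        )
    clipped = np.clip(a, -1.0, 1.0)
    tilt = 180.0 - np.degrees(np.arccos(clipped))
    return TiltSeries(
        cow_id=samples.cow_id,
        epoch_s=samples.epoch_s,
        timestamps=samples.timestamps,
        tilt_deg=tilt,
        n_clipped=int(np.count_nonzero(np.abs(a) > 1.0)),
    )


def segment_days(series: TiltSeries, boundary: dtime = dtime(5, 0)) -> list[DaySegment]:
    """Split a record into experimental days at a local clock boundary.

    Each sample lands in exactly one boundary-to-boundary segment.  Segments
    whose nominal 24-h span is not fully covered by the record (the first
    and/or last day of a deployment) are flagged ``is_partial``.  An empty
    series yields an empty list.
    """
    n = len(series)
    if n == 0:
        return []
    ts = series.timestamps
    bound_ns = (boundary.hour * 3600 + boundary.minute * 60 + boundary.second) * 10**9
    day_ns = 86400 * 10**9
    # floor each timestamp to the most recent boundary instant
    seg_start_i8 = ((ts.asi8 - bound_ns) // day_ns) * day_ns + bound_ns
    segments: list[DaySegment] = []
    record_start, record_end = ts[0], ts[-1]
    for day_index, start_i8 in enumerate(np.unique(seg_start_i8)):
        mask = seg_start_i8 == start_i8
        start = pd.Timestamp(start_i8)
        end = pd.Timestamp(start_i8 + day_ns)
        sub = TiltSeries(
            cow_id=series.cow_id,
            epoch_s=series.epoch_s,
            timestamps=ts[mask],
            tilt_deg=series.tilt_deg[mask],
        )
        partial = record_start > start or record_end < end - pd.Timedelta(
            seconds=series.epoch_s
        )
        segments.append(
            DaySegment(
                cow_id=series.cow_id,
                day_index=day_index,
                start=start,
                end=end,
                series=sub,
                is_partial=bool(partial),
            )
        )
    return segments


def sag_report(series: TiltSeries, open_threshold: float = 30.0) -> QCReport:
    """Count samples with 0 < tilt < threshold: closed door on a sagged mount."""
    if not 0 < open_threshold < 180:
        raise ConfigError("open threshold must lie in (0, 180) degrees")
    tilt = series.tilt_deg
    n_total = len(tilt)
    n_sag = int(np.count_nonzero((tilt > 0) & (tilt < open_threshold)))
    return QCReport(
        n_total=n_total,
        n_sag=n_sag,
        sag_fraction=n_sag / n_total if n_total else 0.0,
    )


def write_tilt_csv(series: TiltSeries, path) -> None:
    """Write the normalized tilt layout: cow_id, ISO-8601 timestamp, tilt_deg."""
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_tilt_csv(path, epoch_s: float | None = None) -> TiltSeries:
    """Read the normalized tilt layout written by :func:`write_tilt_csv`."""
    df = pd.read_csv(path)
    for col in ("cow_id", "timestamp", "tilt_deg"):
        if col not in df.columns:
            raise FormatError(f"column {col!r} not found in {path}")
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    _check_monotone(ts)
    return TiltSeries(
        cow_id=str(df["cow_id"].iloc[0]) if len(df) else "unknown",
        epoch_s=epoch_s if epoch_s is not None else _infer_epoch(ts),
        timestamps=ts,
        tilt_deg=df["tilt_deg"].to_numpy(float),
    )
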