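"""Meal assembly and daily feeding-behavior summaries.

Feeding events (open-door bouts) separated by closed gaps shorter than the
minimum intermeal interval belong to one meal; a gap at or above the MII
splits meals.  Meal length is primarily the wall-clock span from the first
to the last merged feeding event — within-meal closed gaps count toward
length — with the summed open time carried alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class Meal:
    cow_id: str
    day: int
    start: pd.Timestamp
    end: pd.Timestamp
    length_s: float  # span, within-meal gaps included
    open_time_s: float  # summed open-bout time only
    n_events: int


def assemble_meals(
    events: pd.DataFrame,
    mii_minutes: float,
    cow_id: str = "unknown",
    day: int = 0,
) -> list[Meal]:
    """Merge open bouts separated by closed gaps shorter than the MII.

    Gaps >= MII split meals (merge on strict ``gap < MII``).  Bouts in
    different contiguous blocks are never merged: a data gap censors the
    closed time between them, so whether it exceeded the MII is unknown.
    """
    if mii_minutes <= 0:
        raise ConfigError("mii_minutes must be positive")
    mii_s = mii_minutes * 60.0
    opens = events[events["kind"] == "open"]
    if len(opens) == 0:
        return []
    meals: list[Meal] = []
    cur_start = cur_end = None
    cur_open = 0.0
    cur_n = 0
    prev_block = None
    for row in opens.itertuples():
        gap = np.inf if cur_end is None else (row.start - cur_end).total_seconds()
        if cur_end is not None and gap < mii_s and row.block == prev_block:
            cur_end = row.end
            cur_open += row.duration_s
            cur_n += 1
        else:
            if cur_start is not None:
                meals.append(
                    Meal(cow_id, day, cur_start, cur_end,
                         (cur_end - cur_start).total_seconds(), cur_open, cur_n)
                )
            cur_start, cur_end = row.start, row.end
            cur_open, cur_n = row.duration_s, 1
        prev_block = row.block
    meals.append(
        Meal(cow_id, day, cur_start, cur_end,
             (cur_end - cur_start).total_seconds(), cur_open, cur_n)
    )
    return meals


def filter_min_length(
    meals: list[Meal], min_length_s: float = 30.0, epoch_s: float = 30.0
) -> tuple[list[Meal], int]:
    """Drop meals whose span is <= ``min_length_s`` (strict > survives).

    A single-epoch presence cannot be confirmed as feeding for its full
    duration, hence the minimum meal length of > 30 s at a 30-s epoch.
    Returns (kept meals, removed count).
    """
    if min_length_s < epoch_s:
        raise ConfigError("min_length_s must be at least one epoch")
    kept = [m for m in meals if m.length_s > min_length_s]
    return kept, len(meals) - len(kept)


def summarize_days(meals: list[Meal]) -> pd.DataFrame:
    """Per cow-day meal counts and length statistics.

    Returns one row per (cow_id, day): meals_per_day, mean/median meal
    length in minutes and the 10th/90th length percentiles.
    """
    if not meals:
        return pd.DataFrame(
            columns=["cow_id", "day", "meals_per_day", "mean_length_min",
                     "median_length_min", "p10_length_min", "p90_length_min"]
        )
    df = pd.DataFrame(
        {
            "cow_id": [m.cow_id for m in meals],
            "day": [m.day for m in meals],
            "length_min": [m.length_s / 60.0 for m in meals],
        }
    )
    rows = []
    for (cow, day), grp in df.groupby(["cow_id", "day"], sort=True):
        lengths = grp["length_min"].to_numpy()
        rows.append(
            {
                "cow_id": cow,
                "day": day,
                "meals_per_day": len(lengths),
                "mean_length_min": float(np.mean(lengths)),
                "median_length_min": float(np.median(lengths)),
                "p10_length_min": float(np.percentile(lengths, 10)),
                "p90_length_min": float(np.percentile(lengths, 90)),
            }
        )
    return pd.DataFrame(rows)


def pooled_stats(meals: list[Meal]) -> dict:
    """Herd-level pooled statistics: frequency and length mean/SD/percentiles."""
    summary = summarize_days(meals)
    if len(summary) == 0:
        return {"n_meals": 0, "n_cow_days": 0}
    lengths = np.array([m.length_s / 60.0 for m in meals])
    freq = summary["meals_per_day"].to_numpy(float)
    return {
        "n_meals": len(meals),
        "n_cow_days": len(summary),
        "meal_frequency_per_day": {
            "mean": float(freq.mean()),
            "sd": float(freq.std(ddof=1)) if len(freq) > 1 else 0.0,
            "p10": float(np.percentile(freq, 10)),
            "p90": float(np.percentile(freq, 90)),
        },
        "meal_length_min": {
            "mean": float(lengths.mean()),
            "sd": float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
            "p10": float(np.percentile(lengths, 10)),
            "p90": float(np.percentile(lengths, 90)),
        },
    }


def meals_to_frame(meals: list[Meal]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cow_id": [m.cow_id for m in meals],
            "day": [m.day for m in meals],
            "start": [m.start for m in meals],
            "end": [m.end for m in meals],
            "length_s": [m.length_s for m in meals],
            "open_time_s": [m.open_time_s for m in meals],
            "n_events": [m.n_events for m in meals],
        }
    )
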