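"""End-to-end orchestration: tilt records in, meal report out.

Stages: ingest tilt CSVs -> segment days -> classify door states -> run
length encode -> between-feeding intervals -> short-interval filter ->
mixture fit and model selection -> meal criterion -> meal assembly ->
minimum-length filter -> daily and pooled summaries.  Every filter's
in/out counts are accumulated into the report so each record entering the
pipeline is accounted for.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import criterion as mc
from . import metrics, states
from .config import RunConfig
from .errors import CalanFeedError, DataError
from .sensor_io import TiltSeries, read_tilt_csv, sag_report, segment_days


def run_pipeline(
    tilt_series: dict[str, TiltSeries] | None = None,
    input_dir=None,
    config: RunConfig | None = None,
    out_dir=None,
) -> dict:
    """Run the full analysis and return (and optionally write) the report.

    Input is either a mapping of cow id to tilt series or a directory of
    normalized tilt CSVs (one per cow).  With ``out_dir`` set, events,
    intervals, meals, summaries and the mixture/criterion reports are
    written there as CSV/JSON.
    """
    config = config or RunConfig()
    if tilt_series is None:
        if input_dir is None:
            raise DataError("provide tilt_series or input_dir")
        paths = sorted(Path(input_dir).glob("*.csv"))
        if not paths:
            raise DataError(f"no tilt CSV files found in {input_dir}")
        tilt_series = {}
        for p in paths:
            s = read_tilt_csv(p, epoch_s=config.epoch_s)
            tilt_series[s.cow_id if s.cow_id != "unknown" else p.stem] = s

    report: dict = {"counts": {}, "qc": {}}
    all_events, all_intervals = [], []
    n_samples_in = 0
    for cow, series in tilt_series.items():
        n_samples_in += len(series)
        qc = sag_report(series, config.open_threshold_deg)
        report["qc"][cow] = asdict(qc)
        for seg in segment_days(series, config.day_boundary):
            st = states.classify_state(seg.series, config.open_threshold_deg)
            if config.smooth_globally:
                st = states.smooth_mode(st)
            ev = states.run_length_encode(st)
            ev.insert(0, "cow_id", cow)
            ev.insert(1, "day", seg.day_index)
            all_events.append(ev)
            iv = states.extract_intervals(ev)
            if len(iv):
                iv.insert(0, "cow_id", cow)
                iv.insert(1, "day", seg.day_index)
                all_intervals.append(iv)
    if not all_events:
        raise DataError("no samples in any input series")
    events = pd.concat(all_events, ignore_index=True)
    intervals = (
        pd.concat(all_intervals, ignore_index=True)
        if all_intervals
        else pd.DataFrame(columns=["cow_id", "day", "start", "end", "duration_s"])
    )
    report["counts"]["samples_in"] = int(n_samples_in)
    report["counts"]["samples_in_events"] = int(events["n_samples"].sum())
    report["counts"]["raw_intervals"] = int(len(intervals))

    log_iv = mc.prepare_intervals(intervals, min_interval_s=config.min_interval_s)
    report["counts"]["intervals_excluded_short"] = log_iv.n_excluded_short
    report["counts"]["intervals_fitted"] = log_iv.n

    # Epoch-rounded durations put an atom at the cutoff; on small datasets a
    # component can collapse onto it (unbounded likelihood).  Candidates whose
    # restarts all degenerate are skipped and reported, not fatal.
    models, failures = [], {}
    for k in config.k_candidates:
        try:
            models.append(
                mc.fit_mixture(log_iv, K=k, n_restarts=config.n_restarts, seed=config.seed + k)
            )
        except (mc.FitError, mc.InsufficientDataError) as exc:
            failures[f"K{k}"] = str(exc)
    if failures:
        report["mixture_failures"] = failures
    if not any(m.K >= 2 for m in models):
        raise DataError(
            "no multi-component mixture could be fitted: " + "; ".join(failures.values())
        )
    best = models[0] if len(models) == 1 else mc.select_model(models, rule=config.criterion_rule)
    crit = mc.meal_criterion_from_model(best, weighted=config.weighted_intersection)
    report["mixture"] = {
        f"K{m.K}": {
            "weights": m.weights.tolist(),
            "means": m.means.tolist(),
            "sds": m.sds.tolist(),
            "minus2LL": m.minus2LL,
            "AICc": m.aicc,
            "BIC": m.bic,
        }
        for m in models
    }
    report["criterion"] = {
        "rule": config.criterion_rule,
        "selected_K": best.K,
        "C_log_s": crit.C,
        "mii_minutes": crit.mii_minutes,
        "source_components": list(crit.source_components),
    }

    meals = []
    for (cow, day), ev in events.groupby(["cow_id", "day"], sort=True):
        meals.extend(
            metrics.assemble_meals(ev, crit.mii_minutes, cow_id=str(cow), day=int(day))
        )
    report["counts"]["meals_raw"] = len(meals)
    meals, n_removed = metrics.filter_min_length(
        meals, config.min_meal_length_s, config.epoch_s
    )
    report["counts"]["meals_removed_short"] = n_removed
    report["counts"]["meals_final"] = len(meals)
    summary = metrics.summarize_days(meals)
    report["pooled"] = metrics.pooled_stats(meals)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        events.to_csv(out / "events.csv", index=False)
        intervals.to_csv(out / "intervals.csv", index=False)
        metrics.meals_to_frame(meals).to_csv(out / "meals.csv", index=False)
        summary.to_csv(out / "daily_summary.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
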