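import numpy as np
import pandas as pd
import pytest

from calanfeed import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete simulated deployment (2 cows, 2 days)."""
    return simulate_bundle(SimConfig(n_cows=2, n_days=2, seed=42))


@pytest.fixture(scope="session")
def validation_scenario():
    """A noise-free observer-validation session.

    No angle noise, no sag, no observer jitter or recording errors, the
    observer cadence on the sensor epoch grid, and meal-scale bouts only
    (every run far longer than the mode-correction window), so the sensor
    and observer see identical truth.
    """
    return SimConfig(
        n_cows=2,
        n_days=1,
        gap_means=(6.9, 8.77),
        gap_sds=(0.3, 0.63),
        gap_weights=(0.5, 0.5),
        open_bout_median_s=900.0,
        open_bout_sigma_log=0.25,
        angle_noise_sd_deg=0.0,
        sag_rate_deg_per_day=0.0,
        observer_cadence_s=180.0,
        observer_jitter_s=0.0,
        observer_flip_rate=0.0,
        seed=5,
    )


def make_event_table(durations_s, first_kind="open", epoch_s=30.0,
                     t0="2021-06-01 08:00:00", block=0):
    """Alternating event table from a duration list, for hand-built cases."""
    kinds, rows = ["open", "closed"], []
    start = pd.Timestamp(t0)
    k = 0 if first_kind == "open" else 1
    for i, dur in enumerate(durations_s):
        end = start + pd.Timedelta(seconds=dur)
        rows.append(
            {
                "kind": kinds[(k + i) % 2],
                "start": start,
                "end": end,
                "duration_s": float(dur),
                "n_samples": int(round(dur / epoch_s)),
                "block": block,
            }
        )
        start = end
    return pd.DataFrame(rows)
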