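"""Sensor-vs-observer agreement.

Observers note the door state at irregular times (roughly every 2 min 50 s
per door).  Each observation is paired with the mode of the sensor states
in a window around the nearest sensor sample — the windowed mode corrects
for the brief disturbance a walking observer causes — and agreement is
quantified with a 2x2 contingency table, Cohen's kappa with its asymptotic
95% CI, and the positive/negative predictive values of the sensor calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

from .errors import ConfigError, DataError
from .states import StateSeries


@dataclass
class ObserverLog:
    """Manual open/closed annotations for one door; labels are 0/1."""

    door_id: str
    timestamps: pd.DatetimeIndex
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if not np.isin(self.labels, (0, 1)).all():
            raise DataError("observer labels must be binary (0 closed / 1 open)")
        if len(self.labels) != len(self.timestamps):
            raise DataError("label and timestamp lengths differ")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ContingencyTable2x2:
    """Counts by (sensor, observer): n11 both open ... n00 both closed."""

    n11: int
    n10: int  # sensor open, observer closed
    n01: int  # sensor closed, observer open
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]], dtype=float)


@dataclass
class AgreementStats:
    kappa: float
    se_kappa: float
    ci95: tuple[float, float]
    ppv: float
    npv: float
    observed_agreement: float
    expected_agreement: float


def align_to_sensor(
    log: ObserverLog, states: StateSeries, k: int = 5
) -> tuple[pd.DataFrame, int]:
    """Pair each observer record with the windowed-mode sensor state.

    The sensor sample nearest in absolute time is found (ties go to the
    earlier sample) and the mode over the k previous through k following
    samples replaces its raw value; window ties keep the raw nearest value.
    Observer records outside the sensor span are dropped; the drop count is
    returned alongside the pairs frame (columns ``sensor``, ``observer``).
    """
    if k < 0:
        raise ConfigError("window half-width k must be >= 0")
    sts = states.timestamps.asi8
    n = len(sts)
    if n == 0:
        raise DataError("empty sensor series")
    obs_t = log.timestamps.asi8
    in_span = (obs_t >= sts[0]) & (obs_t <= sts[-1])
    n_dropped = int(np.count_nonzero(~in_span))
    obs_t = obs_t[in_span]
    obs_lab = log.labels[in_span]

    right = np.searchsorted(sts, obs_t, side="left")
    right = np.clip(right, 0, n - 1)
    left = np.clip(right - 1, 0, n - 1)
    # ties (equidistant) resolve to the earlier sample via <=
    nearest = np.where(np.abs(obs_t - sts[left]) <= np.abs(sts[right] - obs_t), left, right)

    s = states.state.astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(s)])
    lo = np.maximum(nearest - k, 0)
    hi = np.minimum(nearest + k + 1, n)
    ones = csum[hi] - csum[lo]
    width = hi - lo
    sensor = np.where(2 * ones > width, 1, np.where(2 * ones < width, 0, s[nearest]))
    pairs = pd.DataFrame({"sensor": sensor.astype(np.uint8), "observer": obs_lab})
    return pairs, n_dropped


def contingency(pairs: pd.DataFrame) -> ContingencyTable2x2:
    """Tally (sensor, observer) label combinations into a 2x2 table."""
    if len(pairs) == 0:
        raise DataError("no aligned pairs to tabulate")
    s = pairs["sensor"].to_numpy(int)
    o = pairs["observer"].to_numpy(int)
    return ContingencyTable2x2(
        n11=int(np.count_nonzero((s == 1) & (o == 1))),
        n10=int(np.count_nonzero((s == 1) & (o == 0))),
        n01=int(np.count_nonzero((s == 0) & (o == 1))),
        n00=int(np.count_nonzero((s == 0) & (o == 0))),
    )


def cohens_kappa(table: ContingencyTable2x2) -> AgreementStats:
    """Chance-corrected agreement with asymptotic SE and 95% CI.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement implied by the marginals.  The SE is the
    standard large-sample (delta-method) value for two raters and two
    categories; the CI is kappa +/- 1.96 SE.
    """
    if table.total == 0:
        raise DataError("empty contingency table")
    arr = table.as_array()
    tot = table.total
    p_o = (table.n11 + table.n00) / tot
    row = arr.sum(axis=1) / tot
    col = arr.sum(axis=0) / tot
    p_e = float(row @ col)
    if abs(1.0 - p_e) < 1e-12:
        raise DataError("degenerate marginals: chance agreement is 1, kappa undefined")
    res = _sm_kappa(arr, return_results=True)
    kappa = float(res.kappa)
    se = float(np.sqrt(res.var_kappa))
    ppv, npv = predictive_values(table)
    return AgreementStats(
        kappa=kappa,
        se_kappa=se,
        ci95=(kappa - 1.96 * se, kappa + 1.96 * se),
        ppv=ppv,
        npv=npv,
        observed_agreement=p_o,
        expected_agreement=p_e,
    )


def predictive_values(table: ContingencyTable2x2) -> tuple[float, float]:
    """PPV = P(door open | sensor says open); NPV likewise for closed.

    PPV = n11/(n11+n10), NPV = n00/(n00+n01).  A zero denominator makes
    the corresponding value nan (flagged as undefined rather than raised,
    so a one-sided table still yields the defined half).
    """
    open_total = table.n11 + table.n10
    closed_total = table.n00 + table.n01
    ppv = table.n11 / open_total if open_total else float("nan")
    npv = table.n00 / closed_total if closed_total else float("nan")
    return ppv, npv


def read_observer_csv(path) -> list[ObserverLog]:
    """Read observer annotations (door_id, timestamp, label with open=1)."""
    df = pd.read_csv(path)
    for col in ("door_id", "timestamp", "label"):
        if col not in df.columns:
            raise DataError(f"column {col!r} not found in {path}")
    labels = df["label"].map({"open": 1, "closed": 0, 1: 1, 0: 0})
    if labels.isna().any():
        raise DataError("observer labels must be open/closed (or 1/0)")
    logs = []
    for door, grp in df.assign(_lab=labels).groupby("door_id", sort=True):
        logs.append(
            ObserverLog(
                door_id=str(door),
                timestamps=pd.DatetimeIndex(pd.to_datetime(grp["timestamp"])),
                labels=grp["_lab"].to_numpy(np.uint8),
            )
        )
    return logs


def write_observer_csv(logs: list[ObserverLog], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "door_id": log.door_id,
                "timestamp": log.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                "label": np.where(log.labels == 1, "open", "closed"),
            }
        )
        for log in logs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
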