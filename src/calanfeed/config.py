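"""Run configuration: one YAML file holds every stage threshold.

Defaults are the standard analysis settings (30-degree open threshold,
2-min short-interval filter, >30-s minimum meal length, 05:00 day
boundary, mixture candidates K = 2 and 3 selected by BIC), so an empty
config reproduces the reference analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import time as dtime

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    open_threshold_deg: float = 30.0
    min_interval_s: float = 120.0
    min_meal_length_s: float = 30.0
    day_boundary: dtime = dtime(5, 0)
    epoch_s: float = 30.0
    k_candidates: tuple = (2, 3)
    criterion_rule: str = "bic"  # bic | aicc | m2ll
    n_restarts: int = 10
    smooth_globally: bool = False  # windowed-mode smoothing outside validation
    weighted_intersection: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("open_threshold_deg", "min_interval_s", "min_meal_length_s", "epoch_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if len(self.k_candidates) < 2 and min(self.k_candidates, default=0) < 2:
            raise ConfigError("criterion needs K candidates with at least one K >= 2")
        if self.criterion_rule not in ("bic", "aicc", "m2ll"):
            raise ConfigError("criterion_rule must be bic, aicc or m2ll")


def load_config(path) -> RunConfig:
    """Read a YAML run config; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root in {path} must be a mapping")
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "day_boundary" in raw:
        hh, mm = str(raw["day_boundary"]).split(":")[:2]
        raw["day_boundary"] = dtime(int(hh), int(mm))
    if "k_candidates" in raw:
        raw["k_candidates"] = tuple(int(k) for k in raw["k_candidates"])
    return RunConfig(**raw)


def dump_config(config: RunConfig, path) -> None:
    d = asdict(config)
    d["day_boundary"] = config.day_boundary.strftime("%H:%M")
    d["k_candidates"] = list(config.k_candidates)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
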