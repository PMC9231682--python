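"""Logger mission planning: how long until the memory fills.

Fill time is the sample-slot capacity left after the output header, divided
by the slot consumption rate (samples per second times axes enabled):

    fill_time_s = (memory_units - header_units) / (samples_per_s * n_axes)

Capacity is counted in sample slots, not bytes: the vendor sheet's "~65 k"
memory with a ~500-unit output header at one 3-axis sample per 30 s gives
about 7.5 days of recording, which matches field experience with these
loggers.  The unit interpretation is carried in the report so planners can
sanity-check it against their own hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError


@dataclass
class LoggerSpec:
    """Capacity and mission settings of a data-logging accelerometer."""

    memory_units: float = 65_000.0  # sample-slot capacity
    header_units: float = 500.0  # output-header overhead, in slots
    samples_per_s: float = 1.0 / 30.0
    n_axes: int = 3

    def __post_init__(self) -> None:
        if self.header_units < 0 or self.memory_units <= self.header_units:
            raise ConfigError("need memory_units > header_units >= 0")
        if self.samples_per_s <= 0:
            raise ConfigError("samples_per_s must be positive")
        if self.n_axes < 1:
            raise ConfigError("n_axes must be >= 1")


@dataclass
class FillTime:
    seconds: float
    days: float
    unit_note: str = "capacity interpreted as sample slots"


def fill_time(spec: LoggerSpec) -> FillTime:
    """Mission duration until the logger memory is exhausted."""
    rate = spec.samples_per_s * spec.n_axes
    seconds = (spec.memory_units - spec.header_units) / rate
    return FillTime(seconds=seconds, days=seconds / 86_400.0)
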