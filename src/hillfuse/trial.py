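"""The per-trial data container shared by the io, synthetic and model layers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError
from .signals import StanceCycle, UniformSeries

#: fixed channel names of the delimited trial format (time column excluded)
CHANNEL_NAMES = (
    "angle_rad",
    "grf_v_N",
    "semg_lgs",
    "semg_sol",
    "mt_lgs_mm",
    "mt_sol_mm",
    "moment_Nm",
)

MANDATORY_CHANNELS = ("angle_rad", "grf_v_N", "semg_lgs", "semg_sol", "mt_lgs_mm", "mt_sol_mm")

MUSCLES = ("lgs", "sol")


@dataclass
class GaitTrial:
    """Synchronized channel bundle of one subject x speed.

    ``channels`` maps the fixed channel names to series on a common grid;
    the benchmark moment channel is optional (absent for pure prediction
    inputs).  ``stance`` holds heel-strike/toe-off annotations when known.
    """

    speed: float
    body_mass: float
    channels: dict[str, UniformSeries]
    stance: list[StanceCycle] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_CHANNELS if c not in self.channels]
        if missing:
            raise DataError(f"trial is missing mandatory channels: {missing}")
        lengths = {c: len(s) for c, s in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise DataError(f"channels disagree in length: {lengths}")

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    def channel(self, name: str) -> UniformSeries:
        return self.channels[name]
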