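"""Run configuration: defaults, YAML loading and schema validation.

Every block is a frozen dataclass with physical defaults; unknown keys in a
config file are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .activation import ActivationFilterParams
from .errors import ConfigError

__all__ = [
    "SignalConfig",
    "OptimizerConfig",
    "NoiseConfig",
    "RunConfig",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class SignalConfig:
    """Filtering, segmentation and resampling settings."""

    band_lo: float = 20.0
    band_hi: float = 450.0
    env_cutoff: float = 6.0
    mt_cutoff: float = 30.0
    stance_threshold: float = 20.0
    min_stance_duration: float = 0.2
    fs_model: float = 100.0


@dataclass(frozen=True)
class OptimizerConfig:
    """Bounded least-squares settings (step/function tolerances, iteration cap)."""

    ftol: float = 1e-8
    xtol: float = 1e-8
    gtol: float = 1e-8
    max_iter: int = 200
    method: str = "trf"  # box-capable trust region; "lm-penalty" as alternative


@dataclass(frozen=True)
class NoiseConfig:
    """Synthetic measurement-noise settings.

    sEMG is corrupted by short multiplicative bursts (cross-talk analogue),
    muscle thickness by a slow zero-mean low-frequency wander (the residual
    tracking drift left after key-frame-style correction), and the benchmark
    moment by white noise (inverse-dynamics noise floor).  ``mt_drift_rate``
    is expressed as the equivalent linear drift rate whose ramp over the
    trial has the same RMS as the wander.
    """

    semg_burst_sd: float = 0.40
    semg_burst_rate: float = 0.8  # bursts per second
    semg_burst_duration: float = 0.25  # seconds
    mt_drift_rate: float = 0.03  # mm per second equivalent-RMS wander
    moment_sd: float = 2.0  # N*m

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(
            semg_burst_sd=self.semg_burst_sd * factor,
            semg_burst_rate=self.semg_burst_rate,
            semg_burst_duration=self.semg_burst_duration,
            mt_drift_rate=self.mt_drift_rate * factor,
            moment_sd=self.moment_sd * factor,
        )


ZERO_NOISE = NoiseConfig(semg_burst_sd=0.0, mt_drift_rate=0.0, moment_sd=0.0)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration bundle."""

    signals: SignalConfig = field(default_factory=SignalConfig)
    activation: ActivationFilterParams = field(default_factory=ActivationFilterParams)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {"signals", "activation", "optimizer", "noise", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        signals=_from_dict(SignalConfig, raw.get("signals", {})),
        activation=_from_dict(ActivationFilterParams, raw.get("activation", {})),
        optimizer=_from_dict(OptimizerConfig, raw.get("optimizer", {})),
        noise=_from_dict(NoiseConfig, raw.get("noise", {})),
        seed=int(raw.get("seed", 0)),
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration next to a run's outputs."""
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))
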