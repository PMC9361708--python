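"""Signal conditioning for gait trials.

Raw channels arrive as uniformly sampled series: surface EMG (bandpassed,
rectified and enveloped here), ultrasound-derived muscle thickness (low-pass
filtered here), vertical ground reaction force (used to segment stance
phases) and ankle angle.  All filters are Butterworth applied
forward-backward (zero phase, unit DC gain), so constant inputs pass
through unchanged and no group delay is introduced ahead of the
electromechanical-delay model downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError, InvalidRateError

log = logging.getLogger(__name__)

FILTER_ORDER = 4  # Butterworth order used for every channel

__all__ = [
    "UniformSeries",
    "StanceCycle",
    "bandpass_envelope",
    "normalize_envelope",
    "filter_mt",
    "segment_stance",
    "resample",
]


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled channel.

    Parameters
    ----------
    t0 : float
        Time of the first sample in seconds.
    fs : float
        Sampling rate in Hz, strictly positive.
    values : numpy.ndarray
        Sample values; must be finite and non-empty.
    units : str
        Unit label carried along for bookkeeping (not converted).
    """

    t0: float
    fs: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.fs <= 0:
            raise InvalidRateError(f"sampling rate must be positive, got {self.fs}")
        if v.ndim != 1 or v.size < 1:
            raise DataError("series must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise DataError("series contains non-finite samples")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray, units: str | None = None) -> "UniformSeries":
        return UniformSeries(self.t0, self.fs, values, self.units if units is None else units)

    def same_grid(self, other: "UniformSeries") -> bool:
        return (
            len(self) == len(other)
            and np.isclose(self.fs, other.fs)
            and np.isclose(self.t0, other.t0)
        )


@dataclass(frozen=True)
class StanceCycle:
    """One stance phase: heel-strike sample index up to toe-off sample index."""

    heel_strike_idx: int
    toe_off_idx: int

    def __post_init__(self) -> None:
        if not 0 <= self.heel_strike_idx < self.toe_off_idx:
            raise DataError(
                f"invalid stance cycle [{self.heel_strike_idx}, {self.toe_off_idx})"
            )

    def duration(self, fs: float) -> float:
        return (self.toe_off_idx - self.heel_strike_idx) / fs

    def slice(self) -> slice:
        return slice(self.heel_strike_idx, self.toe_off_idx)


def _check_finite(series: UniformSeries) -> None:
    if not np.all(np.isfinite(series.values)):
        raise DataError("non-finite input samples")


def bandpass_envelope(
    raw_semg: UniformSeries,
    band_lo: float = 20.0,
    band_hi: float = 450.0,
    env_cutoff: float = 6.0,
) -> UniformSeries:
    """Linear envelope of a raw sEMG channel.

    Band-pass (default 20-450 Hz), full-wave rectification, then low-pass
    (default 6 Hz cut-off), all zero-phase.  The envelope is clipped at zero
    since filtfilt ringing can undershoot slightly.
    """
    if not band_lo < band_hi:
        raise ConfigError(f"band_lo must be below band_hi ({band_lo} >= {band_hi})")
    if env_cutoff >= band_lo:
        raise ConfigError("envelope cut-off must sit below the pass band")
    if raw_semg.fs <= 2 * band_hi:
        raise InvalidRateError(
            f"fs={raw_semg.fs} Hz too low for a {band_hi} Hz band edge"
        )
    _check_finite(raw_semg)
    sos_bp = sps.butter(
        FILTER_ORDER, [band_lo, band_hi], btype="bandpass", fs=raw_semg.fs, output="sos"
    )
    band = sps.sosfiltfilt(sos_bp, raw_semg.values)
    rect = np.abs(band)
    sos_lp = sps.butter(FILTER_ORDER, env_cutoff, btype="lowpass", fs=raw_semg.fs, output="sos")
    env = np.clip(sps.sosfiltfilt(sos_lp, rect), 0.0, None)
    return raw_semg.with_values(env)


def normalize_envelope(envelope: UniformSeries, task_peak: float) -> UniformSeries:
    """Normalize an sEMG envelope to the cross-speed task peak, clipped to [0, 1].

    The peak is a per-subject constant taken over every retained sample of
    every speed, so a transient from another trial exceeding it is clipped.
    """
    if task_peak <= 0:
        raise ConfigError(f"task peak must be positive, got {task_peak}")
    _check_finite(envelope)
    u = np.clip(envelope.values / task_peak, 0.0, 1.0)
    return envelope.with_values(u, units="normalized")


def filter_mt(mt_raw: UniformSeries, cutoff: float = 30.0) -> UniformSeries:
    """Zero-phase low-pass of a muscle-thickness trace (default 30 Hz cut-off)."""
    if mt_raw.fs <= 2 * cutoff:
        raise InvalidRateError(f"fs={mt_raw.fs} Hz too low for a {cutoff} Hz cut-off")
    _check_finite(mt_raw)
    sos = sps.butter(FILTER_ORDER, cutoff, btype="lowpass", fs=mt_raw.fs, output="sos")
    return mt_raw.with_values(sps.sosfiltfilt(sos, mt_raw.values))


def segment_stance(
    grf_vertical: UniformSeries,
    threshold: float = 20.0,
    min_duration: float = 0.2,
) -> list[StanceCycle]:
    """Detect stance phases from a vertical GRF channel.

    An upward crossing of ``threshold`` marks heel-strike, the following
    downward crossing marks toe-off.  Cycles shorter than ``min_duration``
    seconds are discarded.  Returns an ordered, non-overlapping list; empty
    (with a log warning) when no loaded period exists.
    """
    _check_finite(grf_vertical)
    loaded = grf_vertical.values > threshold
    edges = np.diff(loaded.astype(np.int8))
    ups = np.flatnonzero(edges == 1) + 1
    downs = np.flatnonzero(edges == -1) + 1
    cycles: list[StanceCycle] = []
    for hs in ups:
        after = downs[downs > hs]
        if after.size == 0:
            break
        to = int(after[0])
        if (to - hs) / grf_vertical.fs >= min_duration:
            cycles.append(StanceCycle(int(hs), to))
    if not cycles:
        log.warning("segment_stance: no stance cycles found (threshold %.1f N)", threshold)
    return cycles


def resample(series: UniformSeries, fs_new: float) -> UniformSeries:
    """Polyphase resampling to a new rate (rational ratio of the old one)."""
    if fs_new <= 0:
        raise InvalidRateError("target rate must be positive")
    if np.isclose(fs_new, series.fs):
        return series
    ratio = Fraction(fs_new / series.fs).limit_denominator(1000)
    out = sps.resample_poly(series.values, ratio.numerator, ratio.denominator)
    return UniformSeries(series.t0, fs_new, out, series.units)
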