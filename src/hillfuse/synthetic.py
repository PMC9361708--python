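"""Synthetic multi-speed treadmill gait trials with known ground truth.

The generator emulates the structure of an instrumented-treadmill walking
study: five belt speeds between 0.50 and 1.50 m/s, roughly 20 s of steady
cycles per speed, stance fraction shrinking and plantarflexor effort growing
with speed.  Channels are produced on the model grid, mutually consistent by
construction: the benchmark moment channel is the package's own forward
model run with known ("true") parameters on the clean channels, so that
calibration and prediction are testable without any experimental deposit.

Measurement noise enters with a distinct failure mode per modality:

* sEMG envelopes get short multiplicative bursts (cross-talk from
  neighbouring muscles inflates the envelope episodically),
* muscle thickness gets a slow zero-mean low-frequency wander (the residual
  tracking error that key-frame correction leaves behind),
* the benchmark moment gets white noise (inverse-dynamics noise floor).

This complementary design gives the sensor-fusion model a mechanism to beat
either single-modality variant, which is the claim the package exists to
exercise.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import PchipInterpolator

from .activation import ActivationFilterParams
from .config import NoiseConfig, SignalConfig
from .errors import ConfigError
from .model import HillModel, task_peaks
from .musculotendon import (
    HnmParameters,
    MuscleConstants,
    MuscleParams,
    default_constants,
)
from .signals import StanceCycle, UniformSeries, segment_stance
from .trial import MUSCLES, GaitTrial

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "default_true_params",
    "make_kinematics",
    "make_activations",
    "forward_generate",
]

GRAVITY = 9.81
LEAD_IN_S = 0.4  # quiet lead-in before the first heel-strike
TAIL_S = 0.3

#: stance-burst shape per muscle: centre, rising width, falling width
#: (as fractions of stance duration) and the linear peak-vs-speed law
_BURST = {
    "lgs": dict(c=0.70, w_rise=0.30, w_fall=0.14, p0=0.30, p1=0.28),
    "sol": dict(c=0.66, w_rise=0.32, w_fall=0.17, p0=0.40, p1=0.25),
}
_SWING_BASELINE = 0.02


def default_true_params(constants: dict[str, MuscleConstants] | None = None) -> HnmParameters:
    """Ground-truth parameter set used by the default study conditions.

    Deliberately off the calibration midpoints but inside every 50-150 %
    box, with interior allocation gains so both modalities genuinely
    contribute to the generated moment.
    """
    c = constants or default_constants()
    return HnmParameters(
        lgs=MuscleParams(A=-1.0, ltsk=0.97 * c["lgs"].lit_ltsk,
                         Fmax=1.15 * c["lgs"].lit_Fmax, delta=0.6),
        sol=MuscleParams(A=-2.0, ltsk=1.04 * c["sol"].lit_ltsk,
                         Fmax=0.85 * c["sol"].lit_Fmax, delta=0.5),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic cohort (one subject by default)."""

    speeds: tuple[float, ...] = (0.50, 0.75, 1.00, 1.25, 1.50)
    n_cycles: int = 16
    fs_model: float = 100.0
    body_mass: float = 78.0  # cohort-mean body mass, kg
    true_params: HnmParameters = field(default_factory=default_true_params)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.speeds):
            raise ConfigError("speeds must be positive")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SyntheticDataset:
    """Generated trials plus the ground truth they were built from."""

    trials: list[GaitTrial]
    truth: dict  # per speed: true activations, clean channels, clean moment
    config: SyntheticConfig


# --------------------------------------------------------------------------- kinematics
def _cycle_layout(speed: float, n_cycles: int, rng: np.random.Generator):
    """Heel-strike times, cycle and stance durations for one trial."""
    base_T = 1.45 - 0.25 * speed
    stance_frac = 0.66 - 0.04 * speed
    T = base_T * (1.0 + rng.normal(0.0, 0.015, size=n_cycles))
    hs = LEAD_IN_S + np.concatenate([[0.0], np.cumsum(T[:-1])])
    return hs, T, stance_frac * T


def make_kinematics(
    speed: float, n_cycles: int, fs: float, seed: int | np.random.Generator
):
    """Ankle angle (rad, dorsiflexion positive) and vertical GRF for one trial.

    The angle traces a small plantarflexion dip after heel-strike, a
    dorsiflexion ramp through mid-stance and a rapid plantarflexion at
    push-off; the GRF is the classic double hump, zero through swing.
    Returns (angle series, grf series, stance cycle list); deterministic for
    a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_cycles == 0:
        empty = UniformSeries(0.0, fs, np.zeros(1))
        return empty.with_values(np.zeros(1), units="rad"), empty.with_values(
            np.zeros(1), units="N"
        ), []

    hs, T, S = _cycle_layout(speed, n_cycles, rng)
    total = hs[-1] + T[-1] + TAIL_S
    t = np.arange(int(round(total * fs))) / fs

    # ankle angle via monotone-time keypoints
    kt, kv = [0.0], [-0.05]
    for k in range(n_cycles):
        dfp = 0.16 + 0.04 * speed + rng.normal(0.0, 0.01)
        pts = [
            (hs[k] + 0.15 * S[k], -0.10 + rng.normal(0.0, 0.005)),
            (hs[k] + 0.45 * S[k], 0.45 * dfp),
            (hs[k] + 0.75 * S[k], dfp),
            (hs[k] + S[k], -0.30 + rng.normal(0.0, 0.01)),
            (hs[k] + S[k] + 0.55 * (T[k] - S[k]), -0.15),
            (hs[k] + T[k], -0.05),
        ]
        for tt, vv in pts:
            kt.append(tt)
            kv.append(vv)
    kt.append(total)
    kv.append(-0.05)
    angle = PchipInterpolator(np.asarray(kt), np.asarray(kv))(t)

    # vertical GRF: two humps inside stance, smooth taper to zero at the edges
    bw = GRAVITY  # per-unit-mass here; scaled by body mass by the caller
    grf = np.zeros_like(t)
    for k in range(n_cycles):
        a1 = 1.02 * (1.0 + rng.normal(0.0, 0.02))
        a2 = 1.08 * (1.0 + rng.normal(0.0, 0.02))
        in_cycle = (t >= hs[k]) & (t < hs[k] + S[k])
        s = (t[in_cycle] - hs[k]) / S[k]
        humps = a1 * np.exp(-(((s - 0.28) / 0.16) ** 2)) + a2 * np.exp(
            -(((s - 0.75) / 0.15) ** 2)
        )
        taper = np.clip(s / 0.04, 0.0, 1.0) * np.clip((1.0 - s) / 0.04, 0.0, 1.0)
        grf[in_cycle] = bw * humps * np.minimum(taper, 1.0)

    stance = [
        StanceCycle(int(round(h * fs)), int(round((h + s_) * fs)))
        for h, s_ in zip(hs, S)
    ]
    return (
        UniformSeries(0.0, fs, angle, "rad"),
        UniformSeries(0.0, fs, grf, "N/kg"),
        stance,
    )


def make_activations(
    speed: float,
    stance: list[StanceCycle],
    n_samples: int,
    fs: float,
    seed: int | np.random.Generator,
) -> dict[str, np.ndarray]:
    """True per-muscle activation drives: unimodal stance bursts in [0, 1].

    The burst rises through mid-stance, peaks near push-off and decays fast
    after toe-off; peak level grows linearly with belt speed, mirroring how
    plantarflexor effort scales with walking speed.  Swing samples stay near
    the resting baseline.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    out = {}
    for m in MUSCLES:
        b = _BURST[m]
        peak = b["p0"] + b["p1"] * speed
        a = np.full(n_samples, _SWING_BASELINE)
        for k, cyc in enumerate(stance):
            hs_t = cyc.heel_strike_idx / fs
            dur = cyc.duration(fs)
            end_t = stance[k + 1].heel_strike_idx / fs if k + 1 < len(stance) else t[-1] + 1 / fs
            pk = peak * (1.0 + rng.normal(0.0, 0.03))
            seg = (t >= hs_t) & (t < end_t)
            s = (t[seg] - hs_t) / dur
            w = np.where(s < b["c"], b["w_rise"], b["w_fall"])
            a[seg] = _SWING_BASELINE + pk * np.exp(-(((s - b["c"]) / w) ** 2))
        out[m] = np.clip(a, 0.0, 1.0)
    return out


# --------------------------------------------------------------------------- channels
def _invert_shape(a1: np.ndarray, A: float) -> np.ndarray:
    """Neural activation whose shape-function image is a1 (inverse of the A-map)."""
    if A == 0.0:
        return a1.copy()
    return np.log1p(a1 * np.expm1(A)) / A


def _drift_field(n: int, fs: float, noise: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """Slow zero-mean thickness-tracking wander, in mm.

    Low-pass filtered white noise (0.15 Hz corner), scaled so its RMS equals
    that of a linear ramp at ``mt_drift_rate`` over the trial duration — the
    knob keeps its mm/s meaning while the corruption stays stationary, the
    way key-frame-corrected tracking error behaves.
    """
    if noise.mt_drift_rate <= 0:
        return np.zeros(n)
    from scipy import signal as sps

    w = rng.normal(0.0, 1.0, n)
    sos = sps.butter(2, 0.15, btype="lowpass", fs=fs, output="sos")
    d = sps.sosfiltfilt(sos, w)
    rms = float(np.sqrt(np.mean(d**2)))
    target = noise.mt_drift_rate * (n / fs) / math.sqrt(3.0)
    return d * (target / rms)


def _burst_field(n: int, fs: float, noise: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative cross-talk bursts: 1 + sum of short positive Hann bumps."""
    field_ = np.ones(n)
    if noise.semg_burst_sd <= 0:
        return field_
    duration = max(int(round(noise.semg_burst_duration * fs)), 2)
    expected = noise.semg_burst_rate * n / fs
    n_bursts = rng.poisson(expected)
    window = np.hanning(duration)
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(n - duration, 1)))
        amp = abs(rng.normal(0.0, noise.semg_burst_sd))
        field_[start : start + duration] += amp * window[: n - start]
    return field_


def forward_generate(
    cfg: SyntheticConfig,
    constants: dict[str, MuscleConstants] | None = None,
    act: ActivationFilterParams | None = None,
) -> SyntheticDataset:
    """Generate the full multi-speed dataset with a model-consistent moment.

    The clean channels (envelope, thickness) encode the same underlying
    activation drive; the benchmark moment is the forward model run on the
    clean channels with ``cfg.true_params``.  Noise is then added to the
    measured channels only.  With all noise terms zero the channels are
    exactly consistent with the forward model.
    """
    constants = constants or default_constants()
    act = act or ActivationFilterParams()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_model

    per_speed: dict[float, dict] = {}
    for speed in cfg.speeds:
        angle, grf_unit, stance = make_kinematics(speed, cfg.n_cycles, fs, rng)
        n = len(angle)
        a_true = make_activations(speed, stance, n, fs, rng)
        env, mt = {}, {}
        for m in MUSCLES:
            env[m] = _invert_shape(a_true[m], cfg.true_params.muscle(m).A)
            b = constants[m].mt_bounds
            mt[m] = b.mt_min + a_true[m] * (b.mt_max - b.mt_min)
        per_speed[speed] = dict(
            angle=angle, grf=grf_unit.with_values(grf_unit.values * cfg.body_mass, "N"),
            stance=stance, a_true=a_true, env=env, mt=mt,
        )

    # normalize the clean envelopes so the cross-speed task peak is exactly 1
    for m in MUSCLES:
        peak = max(float(np.max(d["env"][m])) for d in per_speed.values())
        for d in per_speed.values():
            d["env"][m] = d["env"][m] / peak

    sig = SignalConfig(fs_model=fs)
    model = HillModel(constants, act, sig)

    def build_trial(d: dict, speed: float, env, mt, moment) -> GaitTrial:
        channels = {
            "angle_rad": d["angle"],
            "grf_v_N": d["grf"],
            "semg_lgs": UniformSeries(0.0, fs, env["lgs"], "norm"),
            "semg_sol": UniformSeries(0.0, fs, env["sol"], "norm"),
            "mt_lgs_mm": UniformSeries(0.0, fs, mt["lgs"], "mm"),
            "mt_sol_mm": UniformSeries(0.0, fs, mt["sol"], "mm"),
        }
        if moment is not None:
            channels["moment_Nm"] = UniformSeries(0.0, fs, moment, "N*m")
        stance = segment_stance(channels["grf_v_N"], sig.stance_threshold,
                                sig.min_stance_duration)
        return GaitTrial(speed=speed, body_mass=cfg.body_mass, channels=channels,
                         stance=stance, provenance={"generator": cfg.digest(),
                                                    "speed": speed})

    # clean trials -> forward moment with the true parameters
    clean = {
        v: build_trial(d, v, d["env"], d["mt"], None) for v, d in per_speed.items()
    }
    peaks = task_peaks(list(clean.values()))
    truth: dict[float, dict] = {}
    trials: list[GaitTrial] = []
    for speed, d in per_speed.items():
        prep = model.prepare(clean[speed], peaks)
        m_clean = model.predict_moment(prep, cfg.true_params)

        n = len(d["angle"])
        env_noisy, mt_noisy = {}, {}
        for m in MUSCLES:
            env_noisy[m] = np.clip(d["env"][m] * _burst_field(n, fs, cfg.noise, rng), 0.0, None)
            mt_noisy[m] = d["mt"][m] + _drift_field(n, fs, cfg.noise, rng)
        moment = m_clean + rng.normal(0.0, cfg.noise.moment_sd, size=n)

        trial = build_trial(d, speed, env_noisy, mt_noisy, moment)
        trials.append(trial)
        truth[speed] = dict(
            a_true=d["a_true"], moment_clean=m_clean,
            env_clean=d["env"], mt_clean=d["mt"], stance_true=d["stance"],
        )

    return SyntheticDataset(trials=trials, truth=truth, config=cfg)
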