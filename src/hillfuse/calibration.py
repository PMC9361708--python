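"""Model calibration: dataset assembly, the least-squares objective, fitting
and prediction with a calibrated parameter set.

Calibration minimizes the mean squared difference between the model's net
plantarflexion moment and the inverse-dynamics benchmark over the stance
samples of a block of "steady" gait cycles — 10 cycles of one speed
(single-speed mode) or two cycles from each of five speeds (inter-speed
mode).  The free parameters per muscle are the activation shape factor A,
the tendon slack length, the maximal isometric force and the allocation
gain delta; slack length and force are boxed to 50-150 % of their
literature anchors, A to [-3, 0] and delta to [0, 1], with the search
started from the box midpoints.  Variants pin delta (sEMG-only: 1,
ultrasound-only: 0) or replace the ultrasound activation by seeded uniform
noise (random-signal ablation) while keeping delta free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import OptimizerConfig
from .errors import ConfigError, DataError
from .model import HillModel, PreparedTrial
from .musculotendon import HnmParameters, MuscleConstants, MuscleParams
from .signals import StanceCycle, UniformSeries
from .trial import MUSCLES

log = logging.getLogger(__name__)

__all__ = [
    "CycleBlock",
    "CalibrationDataset",
    "CalibrationResult",
    "ParameterBounds",
    "steady_cycles",
    "build_dataset",
    "objective",
    "calibrate",
    "predict",
    "randomize_a2",
]

VARIANTS = ("fused", "semg_only", "us_only", "random_signal")


@dataclass(frozen=True)
class CycleBlock:
    """One stance cycle of one prepared trial, with provenance."""

    prep: PreparedTrial
    cycle: StanceCycle
    speed: float
    cycle_index: int

    @property
    def target(self) -> np.ndarray:
        if self.prep.moment is None:
            raise DataError("block has no benchmark moment channel")
        return self.prep.moment[self.cycle.slice()]


@dataclass
class CalibrationDataset:
    """Calibration blocks plus the disjoint held-out blocks for prediction."""

    blocks: list[CycleBlock]
    held_out: list[CycleBlock]
    mode: str  # "inter" or "single:<speed>"
    seed: int

    def __post_init__(self) -> None:
        cal = {(b.speed, b.cycle_index) for b in self.blocks}
        held = {(b.speed, b.cycle_index) for b in self.held_out}
        if cal & held:
            raise DataError("calibration and held-out cycles overlap")

    @property
    def n_samples(self) -> int:
        return sum(b.cycle.toe_off_idx - b.cycle.heel_strike_idx for b in self.blocks)

    def provenance(self) -> list[dict]:
        return [
            {"speed": b.speed, "cycle": b.cycle_index, "role": role}
            for role, blocks in (("calibration", self.blocks), ("held_out", self.held_out))
            for b in blocks
        ]


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one calibration run."""

    params: HnmParameters
    objective: float  # (N*m)^2, the mean squared stance residual
    n_evals: int
    converged: bool
    variant: str
    mode: str
    seed: int
    provenance: list[dict] = field(default_factory=list)


def steady_cycles(prep: PreparedTrial, tolerance: float = 0.10) -> list[tuple[int, StanceCycle]]:
    """Indices of cycles whose stance duration is within ±tolerance of the trial median."""
    if not prep.stance:
        return []
    durations = np.array([c.duration(prep.fs) for c in prep.stance])
    med = float(np.median(durations))
    return [
        (i, c)
        for i, (c, d) in enumerate(zip(prep.stance, durations))
        if abs(d - med) <= tolerance * med
    ]


def build_dataset(
    preps: list[PreparedTrial],
    mode: str,
    n_cycles: int = 10,
    seed: int = 0,
    n_held_out: int = 5,
    held_out_start: int = 10,
) -> CalibrationDataset:
    """Assemble a calibration dataset from prepared trials.

    ``mode`` is ``"inter"`` (cycles drawn evenly across all speeds) or
    ``"single:<speed>"`` (all cycles from the trial at that speed).
    Calibration takes the earliest steady cycles of the trials it uses;
    held-out cycles are taken from a fixed later window of EVERY trial
    (positions ``held_out_start`` onward among the steady cycles), so the
    prediction data sits later in each trial than any calibration data and
    the window is identical across calibration modes.  Selection is
    deterministic; the seed is recorded for provenance.
    """
    by_speed = {p.speed: p for p in preps}
    if mode == "inter":
        speeds = sorted(by_speed)
        per_trial, rem = divmod(n_cycles, len(speeds))
        if rem:
            raise ConfigError(
                f"inter-speed mode needs n_cycles divisible by {len(speeds)} speeds"
            )
        wanted = {v: per_trial for v in speeds}
    elif mode.startswith("single:"):
        speed = float(mode.split(":", 1)[1])
        if speed not in by_speed:
            raise ConfigError(f"no trial at speed {speed}; have {sorted(by_speed)}")
        wanted = {speed: n_cycles}
    else:
        raise ConfigError(f"unknown calibration mode {mode!r}")

    blocks: list[CycleBlock] = []
    held: list[CycleBlock] = []
    for speed in sorted(by_speed):
        prep = by_speed[speed]
        steady = steady_cycles(prep)
        n_cal = wanted.get(speed, 0)
        if len(steady) < n_cal:
            raise DataError(
                f"trial at {speed} m/s has {len(steady)} steady cycles, need {n_cal}"
            )
        for i, cyc in steady[:n_cal]:
            blocks.append(CycleBlock(prep, cyc, speed, i))
        start = max(held_out_start, n_cal)
        chosen = steady[start : start + n_held_out]
        if not chosen:
            log.warning("no held-out cycles available at %.2f m/s", speed)
        for i, cyc in chosen:
            held.append(CycleBlock(prep, cyc, speed, i))
    return CalibrationDataset(blocks=blocks, held_out=held, mode=mode, seed=seed)


# --------------------------------------------------------------------- parameter boxes
@dataclass(frozen=True)
class ParameterBounds:
    """Per-muscle calibration boxes, anchored at the literature values."""

    lo: dict[str, tuple[float, float, float, float]]
    hi: dict[str, tuple[float, float, float, float]]

    @classmethod
    def from_constants(cls, constants: dict[str, MuscleConstants]) -> "ParameterBounds":
        lo, hi = {}, {}
        for m in MUSCLES:
            c = constants[m]
            lo[m] = (-3.0, 0.5 * c.lit_ltsk, 0.5 * c.lit_Fmax, 0.0)
            hi[m] = (0.0, 1.5 * c.lit_ltsk, 1.5 * c.lit_Fmax, 1.0)
        return cls(lo, hi)

    def contains(self, params: HnmParameters) -> bool:
        for m in MUSCLES:
            p = params.muscle(m)
            vec = (p.A, p.ltsk, p.Fmax, p.delta)
            if any(v < l - 1e-12 or v > h + 1e-12
                   for v, l, h in zip(vec, self.lo[m], self.hi[m])):
                return False
        return True


def _pack_layout(variant: str) -> list[tuple[str, int]]:
    """(muscle, field-index) layout of the free-parameter vector."""
    fixed_delta = variant in ("semg_only", "us_only")
    layout = []
    for m in MUSCLES:
        for j in range(4):
            if j == 3 and fixed_delta:
                continue
            layout.append((m, j))
    return layout


def _unpack(z: np.ndarray, layout, bounds: ParameterBounds, variant: str) -> HnmParameters:
    """Map the normalized vector z in [0,1]^d back to physical parameters."""
    vals = {m: [None, None, None, None] for m in MUSCLES}
    for zk, (m, j) in zip(z, layout):
        lo, hi = bounds.lo[m][j], bounds.hi[m][j]
        vals[m][j] = lo + float(np.clip(zk, 0.0, 1.0)) * (hi - lo)
    delta_fixed = {"semg_only": 1.0, "us_only": 0.0}.get(variant)
    per = {}
    for m in MUSCLES:
        A, ltsk, Fmax, delta = vals[m]
        per[m] = MuscleParams(A=A, ltsk=ltsk, Fmax=Fmax,
                              delta=delta_fixed if delta is None else delta)
    return HnmParameters(lgs=per["lgs"], sol=per["sol"])


def randomize_a2(prep: PreparedTrial, seed: int) -> PreparedTrial:
    """Replace the ultrasound activation by seeded uniform [0,1] noise (ablation)."""
    rng = np.random.default_rng(seed)
    return prep.with_a2({m: rng.uniform(0.0, 1.0, size=prep.a2[m].size) for m in MUSCLES})


def _effective_blocks(blocks: list[CycleBlock], variant: str, seed: int) -> list[CycleBlock]:
    if variant != "random_signal":
        return blocks
    replaced: dict[int, PreparedTrial] = {}
    out = []
    for b in blocks:
        key = id(b.prep)
        if key not in replaced:
            replaced[key] = randomize_a2(b.prep, seed + int(round(b.speed * 100)))
        out.append(CycleBlock(replaced[key], b.cycle, b.speed, b.cycle_index))
    return out


def _stack_residuals(model: HillModel, blocks: list[CycleBlock],
                     params: HnmParameters) -> np.ndarray:
    res = [model.predict_stance(b.prep, params, b.cycle) - b.target for b in blocks]
    return np.concatenate(res)


def objective(params: HnmParameters, ds: CalibrationDataset, model: HillModel,
              variant: str = "fused") -> float:
    """Mean squared stance-moment residual, in (N*m)^2."""
    blocks = _effective_blocks(ds.blocks, variant, ds.seed)
    r = _stack_residuals(model, blocks, params)
    return float(np.mean(r**2))


def calibrate(
    ds: CalibrationDataset,
    variant: str,
    constants: dict[str, MuscleConstants],
    model: HillModel,
    optimizer: OptimizerConfig | None = None,
) -> CalibrationResult:
    """Bounded least-squares calibration of the parameter set.

    The free parameters are rescaled to the unit box so the trust-region
    steps are well conditioned across quantities of very different
    magnitude.  Residuals are weighted 1/sqrt(N) so the cost equals the
    mean-squared objective.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    opt = optimizer or OptimizerConfig()
    bounds = ParameterBounds.from_constants(constants)
    layout = _pack_layout(variant)
    blocks = _effective_blocks(ds.blocks, variant, ds.seed)
    n_total = sum(b.cycle.toe_off_idx - b.cycle.heel_strike_idx for b in blocks)
    scale = 1.0 / np.sqrt(n_total)

    def residuals(z: np.ndarray) -> np.ndarray:
        params = _unpack(z, layout, bounds, variant)
        return _stack_residuals(model, blocks, params) * scale

    z0 = np.full(len(layout), 0.5)
    # diff_step well above the equilibrium-solver tolerance so finite-difference
    # gradients are not dominated by solver noise
    fit = least_squares(
        residuals, z0, bounds=(np.zeros(len(layout)), np.ones(len(layout))),
        method=opt.method if opt.method == "trf" else "trf",
        ftol=opt.ftol, xtol=opt.xtol, gtol=opt.gtol, diff_step=1e-6,
        max_nfev=opt.max_iter * (len(layout) + 1),
    )
    params = _unpack(fit.x, layout, bounds, variant)
    obj = float(np.sum(fit.fun**2))
    if not fit.success:
        log.warning("calibration (%s, %s) did not converge: %s", variant, ds.mode, fit.message)
    return CalibrationResult(
        params=params, objective=obj, n_evals=int(fit.nfev),
        converged=bool(fit.success), variant=variant, mode=ds.mode, seed=ds.seed,
        provenance=ds.provenance(),
    )


def predict(
    prep: PreparedTrial,
    params: HnmParameters,
    cycles: list[StanceCycle],
    model: HillModel,
    variant: str = "fused",
    seed: int = 0,
) -> list[UniformSeries]:
    """Net-moment prediction over held-out stance cycles.

    For the random-signal ablation the ultrasound activation is replaced by
    fresh seeded noise, mirroring what that variant would see at deployment.
    """
    if variant == "random_signal":
        prep = randomize_a2(prep, seed + 7919 + int(round(prep.speed * 100)))
    out = []
    for cyc in cycles:
        pred = model.predict_stance(prep, params, cyc)
        out.append(UniformSeries(cyc.heel_strike_idx / prep.fs, prep.fs, pred, "N*m"))
    return out
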