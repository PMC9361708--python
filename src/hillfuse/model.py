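"""The assembled Hill-type neuromuscular model.

`HillModel` ties the layers together: channel conditioning (resampling,
thickness filtering, envelope normalization), the activation pathways, the
musculotendon equilibrium and the net-moment sum.  A `PreparedTrial` caches
everything that does not depend on the calibrated parameters (neural
activation N, ultrasound activation a2, the included angle q and stance
annotations) so repeated forward runs during calibration only redo the
parameter-dependent part.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .activation import ActivationFilterParams, neural_activation, us_activation
from .config import SignalConfig
from .errors import DataError
from .musculotendon import (
    HnmParameters,
    MuscleConstants,
    MuscleState,
    _solve_arrays,
    ankle_angle_to_q,
    joint_moment,
    moment_arm,
    mtu_length,
)
from .signals import StanceCycle, UniformSeries, filter_mt, resample, segment_stance
from .trial import MUSCLES, GaitTrial

__all__ = ["PreparedTrial", "HillModel", "task_peaks"]

#: samples of lead-in solved (and discarded) ahead of a stance block so the
#: fascicle-velocity state settles before the scored samples
WARMUP_S = 0.25


@dataclass
class PreparedTrial:
    """Model-grid, parameter-independent view of one trial.

    Besides the conditioned activations, caches the MTU length and moment
    arm per muscle (pure functions of the angle channel), so repeated
    forward runs during calibration skip the geometry entirely.
    """

    speed: float
    body_mass: float
    fs: float
    q: np.ndarray
    N: dict[str, np.ndarray]
    a2: dict[str, np.ndarray]
    l_mt: dict[str, np.ndarray]
    r_mt: dict[str, np.ndarray]
    moment: np.ndarray | None
    stance: list[StanceCycle]

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def with_a2(self, a2: dict[str, np.ndarray]) -> "PreparedTrial":
        return replace(self, a2=a2)


def task_peaks(trials: list[GaitTrial]) -> dict[str, float]:
    """Per-muscle cross-speed task peak of the sEMG envelope channels.

    The maximum over all retained samples of all speeds — the per-subject
    constant every envelope is normalized against.
    """
    peaks = {}
    for m in MUSCLES:
        peaks[m] = max(float(np.max(t.channel(f"semg_{m}").values)) for t in trials)
        if peaks[m] <= 0:
            raise DataError(f"non-positive task peak for {m}")
    return peaks


class HillModel:
    """Forward model from conditioned channels to net plantarflexion moment."""

    def __init__(
        self,
        constants: dict[str, MuscleConstants],
        act: ActivationFilterParams | None = None,
        sig: SignalConfig | None = None,
        moment_arm_convention: str = "derivative",
    ) -> None:
        self.constants = constants
        self.act = act or ActivationFilterParams()
        self.sig = sig or SignalConfig()
        self.convention = moment_arm_convention

    # ------------------------------------------------------------------ prepare
    def prepare(self, trial: GaitTrial, peaks: dict[str, float]) -> PreparedTrial:
        """Condition a trial onto the model grid.

        Envelope channels are normalized to the cross-speed ``peaks``;
        thickness channels are low-pass filtered and mapped to a2; the
        neural activation N (parameter-independent) is computed once.
        Stance cycles come from the trial annotation or, failing that, from
        GRF segmentation.
        """
        fs = self.sig.fs_model

        def on_grid(s: UniformSeries) -> UniformSeries:
            return resample(s, fs)

        angle = on_grid(trial.channel("angle_rad"))
        q = ankle_angle_to_q(angle.values)

        N: dict[str, np.ndarray] = {}
        a2: dict[str, np.ndarray] = {}
        for m in MUSCLES:
            env = on_grid(trial.channel(f"semg_{m}"))
            u = UniformSeries(env.t0, env.fs, np.clip(env.values / peaks[m], 0.0, 1.0))
            N[m] = neural_activation(u, self.act).values
            mt = filter_mt(on_grid(trial.channel(f"mt_{m}_mm")), self.sig.mt_cutoff)
            a2[m] = us_activation(mt, self.constants[m].mt_bounds).values

        moment = None
        if "moment_Nm" in trial.channels:
            moment = on_grid(trial.channel("moment_Nm")).values

        if trial.stance is not None and np.isclose(trial.fs, fs):
            stance = trial.stance
        else:
            grf = on_grid(trial.channel("grf_v_N"))
            stance = segment_stance(
                grf, self.sig.stance_threshold, self.sig.min_stance_duration
            )

        l_mt = {m: mtu_length(q, self.constants[m]) for m in MUSCLES}
        r_mt = {m: moment_arm(q, self.constants[m], self.convention) for m in MUSCLES}
        return PreparedTrial(
            speed=trial.speed, body_mass=trial.body_mass, fs=fs, q=q,
            N=N, a2=a2, l_mt=l_mt, r_mt=r_mt, moment=moment, stance=stance,
        )

    # ------------------------------------------------------------------ forward
    @staticmethod
    def _fused_activation(prep: PreparedTrial, m: str, p, sl: slice) -> np.ndarray:
        """a = delta*a1(N; A) + (1-delta)*a2, pointwise on the slice."""
        n = prep.N[m][sl]
        a1 = n if p.A == 0.0 else np.expm1(p.A * n) / np.expm1(p.A)
        return p.delta * a1 + (1.0 - p.delta) * prep.a2[m][sl]

    def activations(self, prep: PreparedTrial, params: HnmParameters) -> dict[str, np.ndarray]:
        """Fused activation series per muscle at the given parameters."""
        full = slice(0, prep.q.size)
        return {m: self._fused_activation(prep, m, params.muscle(m), full) for m in MUSCLES}

    def muscle_states(
        self, prep: PreparedTrial, params: HnmParameters, sl: slice | None = None
    ) -> dict[str, MuscleState]:
        """Solved musculotendon states over the trial (or a slice of it).

        Uses the geometry cached on the prepared trial; the activation and
        the equilibrium solve run on the requested slice only.
        """
        sl = sl if sl is not None else slice(0, prep.q.size)
        states = {}
        for m in MUSCLES:
            p = params.muscle(m)
            a = self._fused_activation(prep, m, p, sl)
            l_mt = prep.l_mt[m][sl]
            r_mt = prep.r_mt[m][sl]
            lt, lm, phi, vm, fmt, xi, resid = _solve_arrays(
                l_mt, a, prep.dt, self.constants[m], p
            )
            states[m] = MuscleState(
                l_mt=l_mt, r_mt=r_mt, l_t=lt, xi=xi, l_m=lm, phi=phi,
                v_m=vm, F_mt=fmt, moment=fmt * r_mt, residual=resid,
            )
        return states

    def predict_moment(
        self, prep: PreparedTrial, params: HnmParameters, sl: slice | None = None
    ) -> np.ndarray:
        """Net plantarflexion moment series over the trial (or a slice)."""
        return joint_moment(list(self.muscle_states(prep, params, sl).values()))

    def predict_stance(
        self, prep: PreparedTrial, params: HnmParameters, cycle: StanceCycle
    ) -> np.ndarray:
        """Moment over one stance cycle, with a solver lead-in before heel-strike.

        The equilibrium solve carries one sample of state (the previous
        fascicle length); starting a short warm-up ahead of heel-strike lets
        that state settle, and the warm-up samples are discarded.
        """
        warm = int(round(WARMUP_S * prep.fs))
        start = max(0, cycle.heel_strike_idx - warm)
        sl = slice(start, cycle.toe_off_idx)
        pred = self.predict_moment(prep, params, sl)
        return pred[cycle.heel_strike_idx - start:]
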