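"""Musculotendon geometry, force models and the per-sample equilibrium.

The muscle-tendon unit (MTU) spans from a proximal junction A near the knee
to the distal junction B at the heel, both at fixed distances from the ankle
rotation centre O.  With q the included angle at O, the MTU length follows
the law of cosines and the moment arm is its derivative with respect to q.
Inside the MTU a Hill-type muscle (active force-length, force-velocity and
passive-elastic curves, pennated fascicles) acts in series with a nonlinear
tendon whose force-strain law has a quadratic toe region up to a strain of
0.0127 and is linear above.  At every sample the tendon length is solved so
that tendon force equals muscle force projected on the tendon axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np

from . import _kernel
from .errors import AlignmentError, ConfigError
from .activation import MtBounds

log = logging.getLogger(__name__)

__all__ = [
    "CurveParams",
    "MuscleConstants",
    "MuscleParams",
    "HnmParameters",
    "MuscleState",
    "mtu_length",
    "moment_arm",
    "optimal_fascicle_length",
    "pennation",
    "tendon_force",
    "force_length",
    "force_velocity",
    "passive_force",
    "muscle_force",
    "solve_equilibrium",
    "simulate_muscle",
    "joint_moment",
    "default_constants",
    "Q_NEUTRAL",
]

#: included O-angle at the anatomically neutral ankle position
Q_NEUTRAL = math.pi / 2.0

#: residual tolerance of the equilibrium solve, as a fraction of F_max
EQ_FTOL = 1e-9


@dataclass(frozen=True)
class CurveParams:
    """Shape constants of the normalized muscle curves.

    fl_width: variance-like width of the Gaussian active force-length curve.
    fv_shape: curvature of the concentric Hill force-velocity branch.
    fv_ecc_max: eccentric force plateau (in units of maximal isometric force).
    fp_k / fp_ref: gain and strain scale of the exponential passive curve.
    """

    fl_width: float = 0.45
    fv_shape: float = 0.25
    fv_ecc_max: float = 1.4
    fp_k: float = 4.0
    fp_ref: float = 0.6


@dataclass(frozen=True)
class MuscleConstants:
    """Anatomical and physiological constants of one muscle (not calibrated).

    Lengths in metres, angles in radians, forces in newtons.  ``lit_*`` are
    the literature reference values that anchor the 50-150 % calibration
    boxes for tendon slack length and maximal isometric force.
    """

    name: str
    l_OA: float
    l_OB: float
    phi0: float
    l_mo0: float
    lit_ltsk: float
    lit_Fmax: float
    lit_A: float = -1.5
    v_max: float | None = None  # defaults to 10 optimal fascicle lengths / s
    lam: float = 0.15
    mt_bounds: MtBounds | None = None
    curves: CurveParams = field(default_factory=CurveParams)

    def __post_init__(self) -> None:
        for nm in ("l_OA", "l_OB", "l_mo0", "lit_ltsk", "lit_Fmax"):
            if getattr(self, nm) <= 0:
                raise ConfigError(f"{self.name}: {nm} must be positive")
        if not 0.0 <= self.phi0 < math.pi / 2:
            raise ConfigError(f"{self.name}: phi0 outside [0, pi/2)")
        if self.lam < 0:
            raise ConfigError(f"{self.name}: lambda must be nonnegative")
        if self.v_max is None:
            object.__setattr__(self, "v_max", 10.0 * self.l_mo0)


@dataclass(frozen=True)
class MuscleParams:
    """Calibratable parameters of one muscle."""

    A: float
    ltsk: float
    Fmax: float
    delta: float

    def __post_init__(self) -> None:
        if not -3.0 <= self.A <= 0.0:
            raise ConfigError(f"A={self.A} outside [-3, 0]")
        if not 0.0 <= self.delta <= 1.0:
            raise ConfigError(f"delta={self.delta} outside [0, 1]")
        if self.ltsk <= 0 or self.Fmax <= 0:
            raise ConfigError("ltsk and Fmax must be positive")


@dataclass(frozen=True)
class HnmParameters:
    """The calibrated set for the two modelled plantarflexors."""

    lgs: MuscleParams
    sol: MuscleParams

    def muscle(self, name: str) -> MuscleParams:
        return getattr(self, name)


@dataclass(frozen=True)
class MuscleState:
    """Solved per-sample musculotendon state (arrays over a trajectory)."""

    l_mt: np.ndarray
    r_mt: np.ndarray
    l_t: np.ndarray
    xi: np.ndarray
    l_m: np.ndarray
    phi: np.ndarray
    v_m: np.ndarray
    F_mt: np.ndarray
    moment: np.ndarray
    residual: np.ndarray


def mtu_length(q, c: MuscleConstants):
    """MTU length by the law of cosines over the included angle q (rad)."""
    q = np.asarray(q, dtype=float)
    return np.sqrt(c.l_OA**2 + c.l_OB**2 - 2.0 * c.l_OA * c.l_OB * np.cos(q))


def moment_arm(q, c: MuscleConstants, convention: str = "derivative"):
    """Moment arm of the MTU about the ankle.

    ``derivative`` (default) is the exact d(l_mt)/dq of the law-of-cosines
    length: l_OA*l_OB*sin(q)/l_mt.  ``printed`` applies an extra factor 2,
    as sometimes typeset with the law-of-sines derivation; it is kept only
    for literal reproduction and is exactly twice the derivative form.
    """
    q = np.asarray(q, dtype=float)
    r = c.l_OA * c.l_OB * np.sin(q) / mtu_length(q, c)
    if convention == "derivative":
        return r
    if convention == "printed":
        return 2.0 * r
    raise ConfigError(f"unknown moment-arm convention {convention!r}")


def optimal_fascicle_length(a, c: MuscleConstants):
    """Activation-dependent optimal fascicle length l_m0 = l_mo0*(lam*(1-a)+1)."""
    a = np.asarray(a, dtype=float)
    return c.l_mo0 * (c.lam * (1.0 - a) + 1.0)


def pennation(l_m, l_m0, phi0: float):
    """Pennation angle from the constant-thickness assumption.

    phi = arcsin(l_m0*sin(phi0)/l_m).  Arguments above 1 (degenerately short
    fascicle) are clamped to 1 and logged.
    """
    arg = np.asarray(l_m0 * math.sin(phi0) / np.asarray(l_m, dtype=float))
    if np.any(arg > 1.0):
        log.warning("pennation: arcsin argument clamped at 1 for %d samples",
                    int(np.sum(arg > 1.0)))
        arg = np.clip(arg, None, 1.0)
    return np.arcsin(arg)


def tendon_force(xi, Fmax: float):
    """Piecewise tendon force-strain law (quadratic toe, linear above 1.27 % strain)."""
    if Fmax <= 0:
        raise ConfigError("Fmax must be positive")
    xi = np.asarray(xi, dtype=float)
    return np.where(
        xi <= 0.0,
        0.0,
        np.where(xi < 0.0127, 1480.3 * Fmax * xi**2, (37.5 * xi - 0.2375) * Fmax),
    )


def force_length(l_tilde, curves: CurveParams = CurveParams()):
    """Normalized active force-length curve (unimodal, 1 at optimal length)."""
    lt = np.asarray(l_tilde, dtype=float)
    return np.exp(-((lt - 1.0) ** 2) / curves.fl_width)


def force_velocity(v_tilde, curves: CurveParams = CurveParams()):
    """Normalized force-velocity curve; 0 at max shortening, 1 isometric, eccentric plateau."""
    vt = np.atleast_1d(np.asarray(v_tilde, dtype=float))
    out = np.array([_kernel.fv_scalar(v, curves.fv_shape, curves.fv_ecc_max) for v in vt])
    return out if np.ndim(v_tilde) else float(out[0])


def passive_force(l_tilde, curves: CurveParams = CurveParams()):
    """Normalized passive-elastic curve; zero at or below optimal length."""
    lt = np.asarray(l_tilde, dtype=float)
    above = np.clip(lt - 1.0, 0.0, None)
    return np.expm1(curves.fp_k * above / curves.fp_ref) / np.expm1(curves.fp_k)


def muscle_force(l_m, v_m, a, phi, c: MuscleConstants, p: MuscleParams):
    """MTU force (F_ce + F_pe)*cos(phi) at the given fascicle state."""
    l_m0 = optimal_fascicle_length(a, c)
    lt = np.asarray(l_m, dtype=float) / l_m0
    fl = force_length(lt, c.curves)
    fv = force_velocity(np.asarray(v_m, dtype=float) / c.v_max, c.curves)
    fp = passive_force(lt, c.curves)
    return (p.Fmax * fl * fv * np.asarray(a) + p.Fmax * fp) * np.cos(phi)


def _solve_arrays(l_mt: np.ndarray, a: np.ndarray, dt: float,
                  c: MuscleConstants, p: MuscleParams):
    cv = c.curves
    return _kernel.solve_series(
        np.ascontiguousarray(l_mt, dtype=float),
        np.ascontiguousarray(a, dtype=float),
        dt, c.l_mo0, c.phi0, c.lam, c.v_max, p.ltsk, p.Fmax,
        cv.fl_width, cv.fv_shape, cv.fv_ecc_max, cv.fp_k, cv.fp_ref,
        EQ_FTOL * p.Fmax,
    )


def solve_equilibrium(
    l_mt: float,
    a: float,
    prev: MuscleState | None,
    c: MuscleConstants,
    p: MuscleParams,
    dt: float = 0.01,
    q: float | None = None,
) -> MuscleState:
    """Single-sample equilibrium solve (see :func:`simulate_muscle` for series).

    ``prev`` supplies the previous fascicle length for the backward-difference
    velocity; with ``prev=None`` the velocity is zero.  ``q`` (optional)
    only feeds the moment-arm/moment fields.
    """
    if l_mt <= 0.5 * p.ltsk:
        raise ConfigError("l_mt implausibly short against the tendon slack length")
    lm_prev = float(prev.l_m[-1]) if prev is not None else -1.0
    cv = c.curves
    l_m0 = c.l_mo0 * (c.lam * (1.0 - a) + 1.0)
    l_t = _kernel.solve_sample(
        float(l_mt), float(a), lm_prev, dt, l_m0, c.phi0, c.v_max,
        p.ltsk, p.Fmax, cv.fl_width, cv.fv_shape, cv.fv_ecc_max,
        cv.fp_k, cv.fp_ref, EQ_FTOL * p.Fmax,
    )
    h = l_m0 * math.sin(c.phi0)
    w = max(l_mt - l_t, 0.0)
    l_m = math.hypot(w, h)
    phi = math.asin(min(h / l_m, 1.0))
    v_m = 0.0 if lm_prev <= 0 else (l_m - lm_prev) / dt
    xi = (l_t - p.ltsk) / p.ltsk
    f_t = float(tendon_force(xi, p.Fmax))
    f_m = float(muscle_force(l_m, v_m, a, phi, c, p))
    r = float(moment_arm(q, c)) if q is not None else float("nan")
    arr = lambda x: np.asarray([x], dtype=float)
    return MuscleState(
        l_mt=arr(l_mt), r_mt=arr(r), l_t=arr(l_t), xi=arr(xi), l_m=arr(l_m),
        phi=arr(phi), v_m=arr(v_m), F_mt=arr(f_t),
        moment=arr(f_t * r if q is not None else float("nan")),
        residual=arr(f_t - f_m),
    )


def simulate_muscle(
    q: np.ndarray,
    a: np.ndarray,
    dt: float,
    c: MuscleConstants,
    p: MuscleParams,
    convention: str = "derivative",
) -> MuscleState:
    """Solve the equilibrium along a whole (q, a) trajectory of one muscle.

    Returns the solved state with the per-muscle moment F_mt * r_mt.
    """
    q = np.asarray(q, dtype=float)
    a = np.asarray(a, dtype=float)
    if q.shape != a.shape:
        raise AlignmentError("q and a must share a grid")
    l_mt = mtu_length(q, c)
    r_mt = moment_arm(q, c, convention)
    lt, lm, phi, vm, fmt, xi, resid = _solve_arrays(l_mt, a, dt, c, p)
    return MuscleState(
        l_mt=l_mt, r_mt=r_mt, l_t=lt, xi=xi, l_m=lm, phi=phi, v_m=vm,
        F_mt=fmt, moment=fmt * r_mt, residual=resid,
    )


def joint_moment(states: list[MuscleState]) -> np.ndarray:
    """Net plantarflexion moment: sum of F_mt*r_mt over muscles, per sample."""
    if not states:
        raise AlignmentError("need at least one muscle state")
    n = states[0].moment.size
    for s in states[1:]:
        if s.moment.size != n:
            raise AlignmentError("muscle states must share the sampling grid")
    return np.sum([s.moment for s in states], axis=0)


def default_constants() -> dict[str, MuscleConstants]:
    """Reference constants for the two modelled plantarflexors.

    Geometry, optimal fascicle lengths, pennation and the literature anchors
    for tendon slack length and maximal isometric force follow generic
    lower-limb musculoskeletal scaling (gait2392-flavoured values), with
    l_OA/l_OB chosen so each MTU operates near its optimal fascicle length
    at the neutral ankle angle.  Thickness bounds are typical adult values.
    """
    return {
        "lgs": MuscleConstants(
            name="lgs", l_OA=0.452, l_OB=0.062, phi0=math.radians(8.0),
            l_mo0=0.064, lit_ltsk=0.385, lit_Fmax=683.0,
            mt_bounds=MtBounds(12.0, 16.0),
        ),
        "sol": MuscleConstants(
            name="sol", l_OA=0.295, l_OB=0.055, phi0=math.radians(25.0),
            l_mo0=0.050, lit_ltsk=0.250, lit_Fmax=3549.0,
            mt_bounds=MtBounds(25.0, 30.0),
        ),
    }


def ankle_angle_to_q(theta, q_neutral: float = Q_NEUTRAL):
    """Map anatomical ankle angle (rad, dorsiflexion positive) to the included angle q.

    Dorsiflexion stretches the plantarflexor MTUs, so q grows with theta.
    """
    return q_neutral + np.asarray(theta, dtype=float)
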