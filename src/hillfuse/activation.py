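"""Muscle activation models.

Three activation pathways feed the contraction model:

* sEMG route: the normalized envelope u passes through a second-order
  recursive filter with electromechanical delay tau, giving neural
  activation N, then through the nonlinear shape function with factor
  A in [-3, 0] giving a1.
* Ultrasound route: muscle thickness, min-max normalized against
  subject-constant bounds, gives a2 directly.
* Fusion: a = delta*a1 + (1-delta)*a2, a convex combination controlled by
  the allocation gain delta in [0, 1].  delta = 1 reproduces the pure
  sEMG-driven model, delta = 0 the pure ultrasound-driven one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import AlignmentError, ConfigError, StabilityError
from .signals import UniformSeries

__all__ = [
    "ActivationFilterParams",
    "MtBounds",
    "FusionGain",
    "recursion_coeffs",
    "neural_activation",
    "semg_activation",
    "us_activation",
    "fuse_activation",
    "random_activation",
]


@dataclass(frozen=True)
class ActivationFilterParams:
    """Fixed settings of the sEMG-to-neural-activation recursion.

    gamma1/gamma2 are the (real) poles of the second-order recursion, each
    of magnitude < 1 for stability; the coefficient constraint
    alpha - beta1 - beta2 = 1 pins the DC gain at one.  tau is the
    electromechanical delay in seconds (physiological range 30-120 ms);
    shape_A is the nonlinear shape factor in [-3, 0], 0 being linear.
    """

    gamma1: float = 0.5
    gamma2: float = 0.5
    tau: float = 0.040
    shape_A: float = -1.5

    def __post_init__(self) -> None:
        if abs(self.gamma1) >= 1 or abs(self.gamma2) >= 1:
            raise StabilityError("|gamma| must be < 1 for a stable recursion")
        if not 0.030 <= self.tau <= 0.120:
            raise ConfigError(f"tau={self.tau}s outside the 30-120 ms range")
        if not -3.0 <= self.shape_A <= 0.0:
            raise ConfigError(f"shape factor A={self.shape_A} outside [-3, 0]")


@dataclass(frozen=True)
class MtBounds:
    """Subject-constant muscle-thickness bounds in mm (rest to task MVC)."""

    mt_min: float
    mt_max: float

    def __post_init__(self) -> None:
        if not self.mt_max > self.mt_min > 0:
            raise ConfigError(
                f"need mt_max > mt_min > 0, got ({self.mt_min}, {self.mt_max})"
            )


@dataclass(frozen=True)
class FusionGain:
    """Allocation gain delta in [0, 1] weighting sEMG vs ultrasound activation."""

    delta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ConfigError(f"delta={self.delta} outside [0, 1]")


def recursion_coeffs(gamma1: float, gamma2: float) -> tuple[float, float, float]:
    """Coefficients (alpha, beta1, beta2) of the neural-activation recursion.

    beta1 = g1 + g2, beta2 = g1*g2 and alpha = 1 + beta1 + beta2, which makes
    alpha - beta1 - beta2 = 1 hold exactly (unity steady-state gain).
    """
    if abs(gamma1) >= 1 or abs(gamma2) >= 1:
        raise StabilityError("recursion poles must lie strictly inside the unit circle")
    beta1 = gamma1 + gamma2
    beta2 = gamma1 * gamma2
    alpha = 1.0 + beta1 + beta2
    return alpha, beta1, beta2


def neural_activation(u: UniformSeries, p: ActivationFilterParams) -> UniformSeries:
    """Neural activation N from normalized sEMG u.

    N(k) = alpha*u(k - d) - beta1*N(k-1) - beta2*N(k-2) with d = round(tau*fs)
    samples of electromechanical delay, zero initial conditions, and the
    output clipped to [0, 1].  (This is a plain order-2 IIR filter, evaluated
    with scipy's lfilter.)
    """
    alpha, beta1, beta2 = recursion_coeffs(p.gamma1, p.gamma2)
    d = int(round(p.tau * u.fs))
    delayed = np.concatenate([np.zeros(d), u.values])[: len(u)]
    n = sps.lfilter([alpha], [1.0, beta1, beta2], delayed)
    return u.with_values(np.clip(n, 0.0, 1.0), units="activation")


def semg_activation(n: UniformSeries, A: float) -> UniformSeries:
    """Nonlinear neural-to-muscle activation map a1 = (exp(A*N)-1)/(exp(A)-1).

    A in [-3, 0]; A = 0 is evaluated as the linear limit a1 = N.  Endpoint
    identities a1(0) = 0, a1(1) = 1 hold for every A and the map is strictly
    increasing in N.
    """
    if not -3.0 <= A <= 0.0:
        raise ConfigError(f"shape factor A={A} outside [-3, 0]")
    if A == 0.0:
        return n.with_values(n.values.copy())
    a1 = np.expm1(A * n.values) / np.expm1(A)
    return n.with_values(a1)


def us_activation(mt: UniformSeries, b: MtBounds) -> UniformSeries:
    """Ultrasound-derived activation a2 = (MT - MTmin)/(MTmax - MTmin), clipped to [0, 1]."""
    a2 = (mt.values - b.mt_min) / (b.mt_max - b.mt_min)
    return mt.with_values(np.clip(a2, 0.0, 1.0), units="activation")


def fuse_activation(a1: UniformSeries, a2: UniformSeries, g: FusionGain) -> UniformSeries:
    """Weighted activation a = delta*a1 + (1-delta)*a2 (pointwise convex combination)."""
    if not a1.same_grid(a2):
        raise AlignmentError("a1 and a2 must share length, rate and start time")
    a = g.delta * a1.values + (1.0 - g.delta) * a2.values
    return a1.with_values(a)


def random_activation(template: UniformSeries, seed: int) -> UniformSeries:
    """Seeded uniform [0, 1] activation on the grid of ``template``.

    Ablation control: substituting this for the ultrasound-derived a2
    reproduces the fused model's parameter count while removing the
    information the thickness channel carries.
    """
    rng = np.random.default_rng(seed)
    return template.with_values(rng.uniform(0.0, 1.0, size=len(template)), units="activation")
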