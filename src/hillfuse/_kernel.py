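"""Scalar numerics for the musculotendon equilibrium.

Everything here is written as plain scalar math so the whole per-trial
forward pass can be JIT-compiled with numba (used when importable; a pure
Python fallback keeps results identical, just slower).  The public,
array-oriented API lives in :mod:`hillfuse.musculotendon`.

Per sample the unknown is the tendon length l_t.  Geometry closes the
problem: the fascicle height h = l_m0*sin(phi0) is constant at a given
activation (constant-thickness assumption), the horizontal span is
w = l_mt - l_t, so l_m = sqrt(w^2 + h^2), cos(phi) = w/l_m, and
l_t + l_m*cos(phi) = l_mt holds by construction.  The root of
F_t(xi(l_t)) - F_mt(l_t) = 0 is bracketed on [min(0.9*l_sk, l_mt), l_mt]
(the tendon side vanishes at the slack end, the muscle side vanishes at
the pennation-90-degrees end) and solved with a safeguarded
secant/bisection (Illinois) iteration.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def tendon_force_scalar(xi: float, fmax: float) -> float:
    """Piecewise tendon force: slack, quadratic toe, then linear region."""
    if xi <= 0.0:
        return 0.0
    if xi < 0.0127:
        return 1480.3 * fmax * xi * xi
    return (37.5 * xi - 0.2375) * fmax


@njit(cache=True)
def fl_scalar(l_tilde: float, width: float) -> float:
    """Gaussian active force-length curve, unit peak at optimal length."""
    d = l_tilde - 1.0
    return math.exp(-d * d / width)


@njit(cache=True)
def fv_scalar(v_tilde: float, shape: float, ecc_max: float) -> float:
    """Hill force-velocity curve.

    Concentric branch (v_tilde < 0): (1 + v)/(1 - v/shape), zero at the
    maximum shortening velocity v_tilde = -1.  Eccentric branch saturates at
    ecc_max with the slope matched at v_tilde = 0 (C1-continuous).
    """
    if v_tilde <= -1.0:
        return 0.0
    if v_tilde < 0.0:
        return (1.0 + v_tilde) / (1.0 - v_tilde / shape)
    k_ecc = (ecc_max - 1.0) * shape / (shape + 1.0)
    return ecc_max - (ecc_max - 1.0) * math.exp(-v_tilde / k_ecc)


@njit(cache=True)
def fp_scalar(l_tilde: float, k: float, ref: float) -> float:
    """Exponential passive force-length curve, zero at and below optimal length."""
    if l_tilde <= 1.0:
        return 0.0
    return math.expm1(k * (l_tilde - 1.0) / ref) / math.expm1(k)


@njit(cache=True)
def _force_balance(
    l_t: float,
    l_mt: float,
    h: float,
    l_m0: float,
    a: float,
    lm_prev: float,
    dt: float,
    v_max: float,
    l_sk: float,
    fmax: float,
    fl_width: float,
    fv_shape: float,
    fv_ecc: float,
    fp_k: float,
    fp_ref: float,
) -> float:
    """Residual F_t - F_mt at candidate tendon length l_t."""
    w = l_mt - l_t
    if w < 0.0:
        w = 0.0
    l_m = math.sqrt(w * w + h * h)
    cphi = w / l_m
    if lm_prev > 0.0:
        v = (l_m - lm_prev) / dt
    else:
        v = 0.0
    lt_tilde = l_m / l_m0
    f_mt = fmax * (
        a * fl_scalar(lt_tilde, fl_width) * fv_scalar(v / v_max, fv_shape, fv_ecc)
        + fp_scalar(lt_tilde, fp_k, fp_ref)
    ) * cphi
    xi = (l_t - l_sk) / l_sk
    return tendon_force_scalar(xi, fmax) - f_mt


@njit(cache=True)
def solve_sample(
    l_mt: float,
    a: float,
    lm_prev: float,
    dt: float,
    l_m0: float,
    phi0: float,
    v_max: float,
    l_sk: float,
    fmax: float,
    fl_width: float,
    fv_shape: float,
    fv_ecc: float,
    fp_k: float,
    fp_ref: float,
    ftol: float,
) -> float:
    """Tendon length solving F_t(xi) = F_mt at one sample.

    Returns l_t.  The bracket [lo, hi] always straddles the root: the
    residual is <= 0 at the slack end and >= 0 at l_t = l_mt where the
    muscle force component along the tendon vanishes.
    """
    h = l_m0 * math.sin(phi0)
    hi = l_mt
    lo = 0.9 * l_sk
    if lo >= hi:
        lo = 0.5 * l_mt

    args = (l_mt, h, l_m0, a, lm_prev, dt, v_max, l_sk, fmax,
            fl_width, fv_shape, fv_ecc, fp_k, fp_ref)

    # exact slack equilibrium (zero activation, no passive stretch)
    if lo <= l_sk <= hi:
        f_sk = _force_balance(l_sk, *args)
        if abs(f_sk) <= ftol:
            return l_sk

    fa = _force_balance(lo, *args)
    fb = _force_balance(hi, *args)
    if abs(fa) <= ftol:
        return lo
    if abs(fb) <= ftol:
        return hi
    if fa * fb > 0.0:
        # no sign change: boundary fallback with a slack tendon
        return min(l_mt, l_sk)

    # Illinois (modified regula falsi) with bisection safeguard
    x = lo
    for _ in range(200):
        x = hi - fb * (hi - lo) / (fb - fa)
        if not (lo < x < hi):
            x = 0.5 * (lo + hi)
        fx = _force_balance(x, *args)
        if abs(fx) <= ftol or (hi - lo) < 1e-14:
            return x
        if fa * fx < 0.0:
            hi = x
            fb = fx
        else:
            # Illinois scaling keeps the stale endpoint moving
            lo = x
            fa = fx
            fb *= 0.5
    return x


@njit(cache=True)
def solve_series(
    l_mt: np.ndarray,
    a: np.ndarray,
    dt: float,
    l_mo0: float,
    phi0: float,
    lam: float,
    v_max: float,
    l_sk: float,
    fmax: float,
    fl_width: float,
    fv_shape: float,
    fv_ecc: float,
    fp_k: float,
    fp_ref: float,
    ftol: float,
):
    """Sequential equilibrium solve over a sampled trajectory.

    The fascicle velocity at sample k is the backward difference against the
    solved fascicle length at k-1 (zero at the first sample), so the loop is
    inherently sequential.  Returns tendon length, fascicle length,
    pennation, fascicle velocity, musculotendon force, tendon strain and the
    force-balance residual at the solution, all per sample.
    """
    n = l_mt.size
    lt = np.empty(n)
    lm = np.empty(n)
    phi = np.empty(n)
    vm = np.empty(n)
    fmt = np.empty(n)
    xi = np.empty(n)
    resid = np.empty(n)
    lm_prev = -1.0
    for k in range(n):
        l_m0 = l_mo0 * (lam * (1.0 - a[k]) + 1.0)
        h = l_m0 * math.sin(phi0)
        l_t = solve_sample(
            l_mt[k], a[k], lm_prev, dt, l_m0, phi0, v_max, l_sk, fmax,
            fl_width, fv_shape, fv_ecc, fp_k, fp_ref, ftol,
        )
        w = l_mt[k] - l_t
        if w < 0.0:
            w = 0.0
        l_m = math.sqrt(w * w + h * h)
        lt[k] = l_t
        lm[k] = l_m
        phi[k] = math.asin(min(h / l_m, 1.0))
        vm[k] = 0.0 if lm_prev <= 0.0 else (l_m - lm_prev) / dt
        xi[k] = (l_t - l_sk) / l_sk
        f_t = tendon_force_scalar(xi[k], fmax)
        fmt[k] = f_t
        resid[k] = _force_balance(
            l_t, l_mt[k], h, l_m0, a[k], lm_prev, dt, v_max, l_sk, fmax,
            fl_width, fv_shape, fv_ecc, fp_k, fp_ref,
        )
        lm_prev = l_m
    return lt, lm, phi, vm, fmt, xi, resid
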