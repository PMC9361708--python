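"""Musculotendon geometry, force laws and the per-sample equilibrium solve."""

import math

import numpy as np
import pytest

from hillfuse.musculotendon import (
    CurveParams,
    MuscleConstants,
    MuscleParams,
    default_constants,
    force_length,
    force_velocity,
    joint_moment,
    moment_arm,
    mtu_length,
    muscle_force,
    optimal_fascicle_length,
    passive_force,
    pennation,
    simulate_muscle,
    solve_equilibrium,
    tendon_force,
)


@pytest.fixture(scope="module")
def lgs():
    return default_constants()["lgs"]


@pytest.fixture(scope="module")
def sol():
    return default_constants()["sol"]


class TestGeometry:
    def test_right_angle_reduces_to_pythagoras(self, lgs):
        assert mtu_length(math.pi / 2, lgs) == pytest.approx(
            math.hypot(lgs.l_OA, lgs.l_OB), abs=1e-12
        )

    def test_closed_joint_degenerates_to_length_difference(self, lgs):
        assert mtu_length(1e-9, lgs) == pytest.approx(abs(lgs.l_OA - lgs.l_OB), abs=1e-9)

    def test_law_of_cosines_direct_value(self):
        c = MuscleConstants(name="x", l_OA=0.40, l_OB=0.06, phi0=0.1,
                            l_mo0=0.05, lit_ltsk=0.3, lit_Fmax=1000.0)
        # independent evaluation of sqrt(0.40^2 + 0.06^2 - 2*0.40*0.06*cos 1.9)
        assert mtu_length(1.9, c) == pytest.approx(0.4232232262169081, abs=1e-12)

    def test_moment_arm_vanishes_at_degenerate_angles(self, lgs):
        for conv in ("derivative", "printed"):
            assert moment_arm(1e-12, lgs, conv) == pytest.approx(0.0, abs=1e-10)
            assert moment_arm(math.pi, lgs, conv) == pytest.approx(0.0, abs=1e-10)

    def test_derivative_convention_matches_numeric_differentiation(self, lgs, sol):
        q = np.linspace(0.1, 3.0, 100)
        h = 1e-6
        for c in (lgs, sol):
            numeric = (mtu_length(q + h, c) - mtu_length(q - h, c)) / (2 * h)
            assert np.max(np.abs(moment_arm(q, c, "derivative") - numeric)) < 1e-8

    def test_printed_convention_is_twice_the_derivative(self, lgs):
        q = np.linspace(0.1, 3.0, 50)
        assert np.allclose(moment_arm(q, lgs, "printed"),
                           2.0 * moment_arm(q, lgs, "derivative"), rtol=1e-14)


class TestFascicleGeometry:
    def test_optimal_length_shrinks_with_activation(self, lgs):
        assert optimal_fascicle_length(1.0, lgs) == pytest.approx(lgs.l_mo0)
        assert optimal_fascicle_length(0.0, lgs) == pytest.approx(1.15 * lgs.l_mo0)
        assert optimal_fascicle_length(0.5, lgs) == pytest.approx(1.075 * lgs.l_mo0)

    def test_pennation_identities(self):
        assert pennation(0.05, 0.05, 0.3) == pytest.approx(0.3)
        assert pennation(50.0, 0.05, 0.3) == pytest.approx(0.0, abs=1e-3)
        assert pennation(0.10, 0.05, 0.2) == pytest.approx(
            math.asin(math.sin(0.2) / 2), abs=1e-12
        )

    def test_degenerate_short_fascicle_clamped(self, caplog):
        # l_m shorter than the constant-thickness height: arcsin arg > 1
        phi = pennation(0.01, 0.05, 1.2)
        assert phi == pytest.approx(math.pi / 2)


class TestTendonForce:
    def test_slack_branch_is_zero(self):
        assert tendon_force(-0.01, 1000.0) == 0.0
        assert tendon_force(0.0, 1000.0) == 0.0

    def test_branches_agree_at_transition_strain(self):
        quad = 1480.3 * 0.0127**2
        lin = 37.5 * 0.0127 - 0.2375
        assert abs(quad - lin) / lin < 1e-4
        assert tendon_force(0.0127, 1.0) == pytest.approx(lin)

    def test_linear_branch_value(self):
        assert tendon_force(0.05, 1000.0) == pytest.approx(1637.5)

    def test_nondecreasing_over_working_range(self):
        xi = np.linspace(-0.02, 0.1, 500)
        f = tendon_force(xi, 1.0)
        assert np.all(np.diff(f) >= 0)

    def test_slope_gap_at_transition_below_half_percent(self):
        # quadratic-branch slope 2*1480.3*0.0127 vs linear slope 37.5
        assert abs(2 * 1480.3 * 0.0127 - 37.5) / 37.5 < 0.005


class TestMuscleCurves:
    def test_normalization_conventions(self):
        cv = CurveParams()
        assert force_length(1.0, cv) == pytest.approx(1.0)
        assert force_velocity(0.0, cv) == pytest.approx(1.0)
        assert passive_force(1.0, cv) == pytest.approx(0.0)

    def test_max_shortening_velocity_kills_active_force(self):
        assert force_velocity(-1.0) == 0.0
        assert force_velocity(-1.5) == 0.0

    def test_gaussian_force_length_is_symmetric(self):
        assert force_length(0.8) == pytest.approx(force_length(1.2), rel=1e-12)

    def test_eccentric_plateau_bounded(self):
        cv = CurveParams()
        v = np.linspace(0.0, 5.0, 200)
        fv = force_velocity(v, cv)
        assert np.all(fv <= cv.fv_ecc_max + 1e-12)
        assert np.all(np.diff(fv) >= 0)

    def test_passive_force_strictly_increasing_above_optimal(self):
        lt = np.linspace(1.0, 1.5, 100)
        fp = passive_force(lt)
        assert np.all(np.diff(fp) > 0)
        assert np.all(passive_force(np.linspace(0.5, 1.0, 20)) == 0.0)


class TestMuscleForce:
    def test_passive_only_states(self, lgs):
        p = MuscleParams(A=-1.5, ltsk=lgs.lit_ltsk, Fmax=lgs.lit_Fmax, delta=0.5)
        l_m0_rest = optimal_fascicle_length(0.0, lgs)
        assert muscle_force(l_m0_rest, 0.0, 0.0, 0.0, lgs, p) == pytest.approx(0.0)

    def test_fully_active_isometric_at_optimal_gives_fmax(self, lgs):
        p = MuscleParams(A=-1.5, ltsk=lgs.lit_ltsk, Fmax=lgs.lit_Fmax, delta=0.5)
        f = muscle_force(lgs.l_mo0, 0.0, 1.0, 0.0, lgs, p)
        assert f == pytest.approx(p.Fmax, rel=1e-12)

    def test_max_shortening_leaves_only_passive(self, lgs):
        p = MuscleParams(A=-1.5, ltsk=lgs.lit_ltsk, Fmax=lgs.lit_Fmax, delta=0.5)
        l_m = 1.2 * optimal_fascicle_length(1.0, lgs)
        phi = 0.2
        f = muscle_force(l_m, -lgs.v_max, 1.0, phi, lgs, p)
        lt = l_m / optimal_fascicle_length(1.0, lgs)
        expected = p.Fmax * passive_force(lt, lgs.curves) * math.cos(phi)
        assert f == pytest.approx(expected, rel=1e-12)


def oracle_bisect(l_mt, a, c, p, n_iter=200):
    """Independent equilibrium oracle: plain bisection on the force balance."""
    l_m0 = c.l_mo0 * (c.lam * (1.0 - a) + 1.0)
    h = l_m0 * math.sin(c.phi0)

    def balance(l_t):
        w = max(l_mt - l_t, 0.0)
        l_m = math.hypot(w, h)
        phi = math.asin(min(h / l_m, 1.0))
        f_m = muscle_force(l_m, 0.0, a, phi, c, p)
        xi = (l_t - p.ltsk) / p.ltsk
        return float(tendon_force(xi, p.Fmax)) - float(f_m)

    lo, hi = 0.9 * p.ltsk, l_mt
    if balance(lo) * balance(hi) > 0:
        return min(l_mt, p.ltsk)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if balance(lo) * balance(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestEquilibrium:
    def test_slack_equilibrium_is_exact(self, sol):
        p = MuscleParams(A=-1.5, ltsk=sol.lit_ltsk, Fmax=sol.lit_Fmax, delta=0.5)
        # l_mt short enough that the relaxed fascicle carries no passive force
        l_mt = p.ltsk + 0.8 * optimal_fascicle_length(0.0, sol)
        st = solve_equilibrium(l_mt, 0.0, None, sol, p)
        assert st.l_t[0] == p.ltsk
        assert st.F_mt[0] == 0.0

    @pytest.mark.parametrize("a", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_construction_identity_holds(self, lgs, a):
        p = MuscleParams(A=-1.5, ltsk=lgs.lit_ltsk, Fmax=lgs.lit_Fmax, delta=0.5)
        l_mt = mtu_length(1.65, lgs)
        st = solve_equilibrium(l_mt, a, None, lgs, p)
        assert abs(st.l_mt[0] - (st.l_t[0] + st.l_m[0] * math.cos(st.phi[0]))) < 1e-9

    def test_pennation_identity_after_solve(self, sol):
        p = MuscleParams(A=-1.5, ltsk=sol.lit_ltsk, Fmax=sol.lit_Fmax, delta=0.5)
        for a in (0.2, 0.6, 1.0):
            l_m0 = optimal_fascicle_length(a, sol)
            st = solve_equilibrium(mtu_length(1.7, sol), a, None, sol, p)
            assert abs(st.l_m[0] * math.sin(st.phi[0]) - l_m0 * math.sin(sol.phi0)) < 1e-12

    def test_strain_monotone_in_activation_and_matches_oracle(self, lgs, sol):
        for c in (lgs, sol):
            p = MuscleParams(A=-1.5, ltsk=c.lit_ltsk, Fmax=c.lit_Fmax, delta=0.5)
            l_mt = mtu_length(1.75, c)
            xis, lts = [], []
            for a in np.linspace(0.0, 1.0, 5):
                st = solve_equilibrium(l_mt, float(a), None, c, p)
                xis.append(st.xi[0])
                lts.append(st.l_t[0])
                assert abs(st.l_t[0] - oracle_bisect(l_mt, float(a), c, p)) < 1e-7
            assert np.all(np.diff(xis) >= -1e-12)

    def test_low_activation_limit_approaches_rigid_tendon_split(self, sol):
        # with no force demand the tendon stays at slack length and the
        # fascicle projection takes up exactly the remaining span
        p = MuscleParams(A=-1.5, ltsk=sol.lit_ltsk, Fmax=sol.lit_Fmax, delta=0.5)
        l_mt = p.ltsk + 0.7 * optimal_fascicle_length(0.0, sol)
        st = solve_equilibrium(l_mt, 0.0, None, sol, p)
        assert st.l_m[0] * math.cos(st.phi[0]) == pytest.approx(l_mt - p.ltsk, abs=1e-12)

    def test_residual_tolerance_on_trajectory(self, lgs):
        p = MuscleParams(A=-1.0, ltsk=0.97 * lgs.lit_ltsk, Fmax=1.1 * lgs.lit_Fmax, delta=0.5)
        q = 1.571 + 0.25 * np.sin(np.linspace(0, 4 * np.pi, 400))
        a = 0.5 + 0.45 * np.sin(np.linspace(0, 6 * np.pi, 400)) ** 2
        st = simulate_muscle(q, a, 0.01, lgs, p)
        assert np.max(np.abs(st.residual)) <= 1e-6 * p.Fmax
        assert np.max(np.abs(st.l_mt - (st.l_t + st.l_m * np.cos(st.phi)))) < 1e-9


class TestJointMoment:
    def test_additivity_and_trivial_products(self, lgs, sol):
        p = MuscleParams(A=-1.5, ltsk=lgs.lit_ltsk, Fmax=lgs.lit_Fmax, delta=0.5)
        s1 = simulate_muscle(np.full(10, 1.6), np.full(10, 0.5), 0.01, lgs, p)
        p2 = MuscleParams(A=-1.5, ltsk=sol.lit_ltsk, Fmax=sol.lit_Fmax, delta=0.5)
        s2 = simulate_muscle(np.full(10, 1.6), np.full(10, 0.5), 0.01, sol, p2)
        total = joint_moment([s1, s2])
        assert np.allclose(total, s1.moment + s2.moment)
        assert np.all(total >= 0)
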