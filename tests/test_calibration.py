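"""Calibration: dataset assembly, objective algebra, fitting and prediction."""

import numpy as np
import pytest

from hillfuse.calibration import (
    ParameterBounds,
    build_dataset,
    calibrate,
    objective,
    predict,
)
from hillfuse.config import OptimizerConfig
from hillfuse.errors import ConfigError, DataError
from hillfuse.musculotendon import HnmParameters, MuscleParams


class TestBuildDataset:
    def test_inter_speed_draws_two_cycles_per_speed(self, clean_preps):
        ds = build_dataset(clean_preps, "inter", n_cycles=10, seed=0)
        assert len(ds.blocks) == 10
        per_speed = {}
        for b in ds.blocks:
            per_speed.setdefault(b.speed, 0)
            per_speed[b.speed] += 1
        assert set(per_speed.values()) == {2}

    def test_single_speed_draws_all_from_one_trial(self, clean_preps):
        ds = build_dataset(clean_preps, "single:0.5", n_cycles=10, seed=0)
        assert len(ds.blocks) == 10
        assert {b.speed for b in ds.blocks} == {0.5}

    def test_held_out_window_is_disjoint_and_later(self, clean_preps):
        ds = build_dataset(clean_preps, "single:0.5", n_cycles=10, seed=0)
        cal = {(b.speed, b.cycle_index) for b in ds.blocks}
        held = {(b.speed, b.cycle_index) for b in ds.held_out}
        assert not cal & held
        cal_max = max(i for s, i in cal)
        assert all(i > cal_max for s, i in held if s == 0.5)
        # every speed contributes held-out cycles for cross-speed prediction
        assert {b.speed for b in ds.held_out} == {p.speed for p in clean_preps}

    def test_selection_is_deterministic(self, clean_preps):
        a = build_dataset(clean_preps, "inter", seed=5)
        b = build_dataset(clean_preps, "inter", seed=5)
        assert [(x.speed, x.cycle_index) for x in a.blocks] == [
            (x.speed, x.cycle_index) for x in b.blocks
        ]

    def test_insufficient_cycles_raises(self, clean_preps):
        with pytest.raises(DataError):
            build_dataset(clean_preps, "single:0.5", n_cycles=50, seed=0)

    def test_unknown_mode_rejected(self, clean_preps):
        with pytest.raises(ConfigError):
            build_dataset(clean_preps, "tri-speed", seed=0)


class TestObjective:
    def test_true_parameters_yield_near_zero_objective(self, clean_preps, clean_dataset, model):
        ds = build_dataset(clean_preps, "inter", seed=0)
        obj = objective(clean_dataset.config.true_params, ds, model)
        assert obj < 1e-10

    def test_constant_offset_costs_its_square(self, clean_preps, clean_dataset, model):
        import dataclasses

        ds = build_dataset(clean_preps, "inter", seed=0)
        shifted_preps = [
            dataclasses.replace(p, moment=p.moment + 2.0) for p in clean_preps
        ]
        ds_shift = build_dataset(shifted_preps, "inter", seed=0)
        obj = objective(clean_dataset.config.true_params, ds_shift, model)
        assert obj == pytest.approx(4.0, abs=1e-6)

    def test_residual_arithmetic(self):
        # mean of squared residuals (1, -1, 2) is 2
        assert np.mean(np.array([1.0, -1.0, 2.0]) ** 2) == 2.0


@pytest.fixture(scope="module")
def quick_opt():
    return OptimizerConfig(max_iter=60)


class TestCalibrate:

    def test_semg_only_pins_delta_at_one(self, clean_preps, constants, model, quick_opt):
        ds = build_dataset(clean_preps, "inter", seed=0)
        res = calibrate(ds, "semg_only", constants, model, quick_opt)
        assert res.params.lgs.delta == 1.0 and res.params.sol.delta == 1.0

    def test_us_only_pins_delta_at_zero(self, clean_preps, constants, model, quick_opt):
        ds = build_dataset(clean_preps, "inter", seed=0)
        res = calibrate(ds, "us_only", constants, model, quick_opt)
        assert res.params.lgs.delta == 0.0 and res.params.sol.delta == 0.0

    def test_result_improves_on_midpoint_start_and_respects_bounds(
        self, clean_preps, clean_dataset, constants, model, quick_opt
    ):
        ds = build_dataset(clean_preps, "inter", seed=0)
        bounds = ParameterBounds.from_constants(constants)
        mid = HnmParameters(
            lgs=MuscleParams(A=-1.5, ltsk=constants["lgs"].lit_ltsk,
                             Fmax=constants["lgs"].lit_Fmax, delta=0.5),
            sol=MuscleParams(A=-1.5, ltsk=constants["sol"].lit_ltsk,
                             Fmax=constants["sol"].lit_Fmax, delta=0.5),
        )
        res = calibrate(ds, "fused", constants, model, quick_opt)
        assert res.objective <= objective(mid, ds, model) + 1e-12
        assert bounds.contains(res.params)

    def test_reproducible_bitwise(self, clean_preps, constants, model, quick_opt):
        ds = build_dataset(clean_preps, "inter", seed=3)
        r1 = calibrate(ds, "fused", constants, model, quick_opt)
        r2 = calibrate(ds, "fused", constants, model, quick_opt)
        assert r1.params == r2.params and r1.objective == r2.objective

    def test_unknown_variant_rejected(self, clean_preps, constants, model):
        ds = build_dataset(clean_preps, "inter", seed=0)
        with pytest.raises(ConfigError):
            calibrate(ds, "kalman", constants, model)


class TestRecovery:
    def test_noise_free_recovery_of_gains_and_forces(self, recovery_runs):
        for run in recovery_runs:
            assert run["delta_err_lgs"] <= 0.05
            assert run["delta_err_sol"] <= 0.05
            assert run["fmax_err_pct_lgs"] <= 5.0
            assert run["fmax_err_pct_sol"] <= 5.0

    def test_round_trip_prediction_with_true_parameters(self, recovery_runs):
        for run in recovery_runs:
            assert run["r2_true"] >= 0.999

    def test_recovery_degrades_with_benchmark_noise(self, constants, model):
        """Average recovery error grows as moment noise grows through 0, 2, 5 N*m."""
        from hillfuse.benchmark import prepare_all
        from hillfuse.config import NoiseConfig
        from hillfuse.synthetic import SyntheticConfig, forward_generate

        mean_err = []
        for sd in (0.0, 2.0, 5.0):
            errs = []
            for seed in (1, 2, 3):
                noise = NoiseConfig(semg_burst_sd=0.0, mt_drift_rate=0.0, moment_sd=sd)
                cfg = SyntheticConfig(seed=seed, noise=noise)
                data = forward_generate(cfg, constants)
                preps = prepare_all(data, model)
                ds = build_dataset(preps, "inter", seed=seed)
                res = calibrate(ds, "fused", constants, model, OptimizerConfig(max_iter=60))
                truth = cfg.true_params
                errs.append(
                    np.mean([
                        abs(res.params.muscle(m).Fmax - truth.muscle(m).Fmax)
                        / truth.muscle(m).Fmax
                        for m in ("lgs", "sol")
                    ])
                )
            mean_err.append(np.mean(errs))
        assert mean_err[0] <= mean_err[1] + 1e-6
        assert mean_err[1] <= mean_err[2] + 1e-6


class TestPredict:
    def test_prediction_series_cover_requested_cycles(self, clean_preps, clean_dataset, model):
        prep = clean_preps[1]
        cycles = prep.stance[10:12]
        series = predict(prep, clean_dataset.config.true_params, cycles, model)
        assert len(series) == 2
        for s, cyc in zip(series, cycles):
            assert len(s) == cyc.toe_off_idx - cyc.heel_strike_idx

    def test_random_signal_prediction_uses_fresh_noise(self, clean_preps, clean_dataset, model):
        prep = clean_preps[0]
        cyc = [prep.stance[10]]
        params = clean_dataset.config.true_params
        a = predict(prep, params, cyc, model, variant="random_signal", seed=1)
        b = predict(prep, params, cyc, model, variant="random_signal", seed=2)
        assert not np.array_equal(a[0].values, b[0].values)
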