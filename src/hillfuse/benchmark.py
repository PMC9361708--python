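"""End-to-end synthetic experiments: calibrate, predict held-out cycles, score.

This is the harness behind the package's headline comparisons — the fused
sEMG+ultrasound model against each single-modality variant and the
random-signal ablation, under single-speed and inter-speed calibration.
Everything is driven by one integer seed, so runs are exactly repeatable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import ActivationFilterParams
from .calibration import (
    CalibrationDataset,
    CalibrationResult,
    build_dataset,
    calibrate,
    predict,
)
from .config import NoiseConfig, OptimizerConfig, SignalConfig, ZERO_NOISE
from .evaluation import metrics, peak_moment
from .model import HillModel, PreparedTrial, task_peaks
from .musculotendon import MuscleConstants, default_constants
from .synthetic import SyntheticConfig, SyntheticDataset, forward_generate
from .trial import MUSCLES

__all__ = ["StudyResult", "prepare_all", "run_study", "recovery_experiment"]


@dataclass
class StudyResult:
    """Held-out prediction scores of one synthetic study run."""

    table: pd.DataFrame  # variant, mode, speed, rmse, n_rmse, bm_rmse, r2
    calibrations: dict[tuple[str, str], CalibrationResult]
    peak: float
    seed: int


def prepare_all(data: SyntheticDataset, model: HillModel) -> list[PreparedTrial]:
    """Condition every generated trial onto the model grid, as an analyst would."""
    peaks = task_peaks(data.trials)
    return [model.prepare(t, peaks) for t in data.trials]


def _held_out_metrics(
    ds: CalibrationDataset,
    result: CalibrationResult,
    model: HillModel,
    peak: float,
    body_mass: float,
) -> list[dict]:
    """Pooled per-speed metrics over the held-out cycles."""
    rows = []
    for speed in sorted({b.speed for b in ds.held_out}):
        blocks = [b for b in ds.held_out if b.speed == speed]
        preds, truths = [], []
        for b in blocks:
            series = predict(b.prep, result.params, [b.cycle], model,
                             variant=result.variant, seed=ds.seed)
            preds.append(series[0].values)
            truths.append(b.target)
        mb = metrics(np.concatenate(preds), np.concatenate(truths), peak, body_mass)
        rows.append({
            "variant": result.variant, "mode": result.mode, "speed": speed,
            "rmse": mb.rmse, "n_rmse": mb.n_rmse, "bm_rmse": mb.bm_rmse, "r2": mb.r2,
        })
    return rows


def run_study(
    seed: int,
    variants: tuple[str, ...] = ("fused", "semg_only", "us_only"),
    modes: tuple[str, ...] = ("inter",),
    noise: NoiseConfig | None = None,
    constants: dict[str, MuscleConstants] | None = None,
    optimizer: OptimizerConfig | None = None,
    n_cycles: int = 16,
) -> StudyResult:
    """Generate one synthetic subject, calibrate every (variant, mode) cell,
    and score held-out stance cycles at all five speeds.

    Defaults reproduce the package's standard study conditions (moderate
    complementary noise).  Returns the tidy held-out metric table plus the
    calibration results themselves.
    """
    constants = constants or default_constants()
    cfg = SyntheticConfig(seed=seed, n_cycles=n_cycles,
                          noise=noise if noise is not None else NoiseConfig())
    data = forward_generate(cfg, constants)
    model = HillModel(constants, ActivationFilterParams(),
                      SignalConfig(fs_model=cfg.fs_model))
    preps = prepare_all(data, model)
    peak = peak_moment(preps)
    body_mass = cfg.body_mass

    rows: list[dict] = []
    calibrations: dict[tuple[str, str], CalibrationResult] = {}
    for mode in modes:
        ds = build_dataset(preps, mode, seed=seed)
        for variant in variants:
            result = calibrate(ds, variant, constants, model, optimizer)
            calibrations[(variant, mode)] = result
            rows.extend(_held_out_metrics(ds, result, model, peak, body_mass))
    return StudyResult(table=pd.DataFrame(rows), calibrations=calibrations,
                       peak=peak, seed=seed)


def recovery_experiment(
    seed: int,
    constants: dict[str, MuscleConstants] | None = None,
    optimizer: OptimizerConfig | None = None,
) -> dict:
    """Noise-free parameter recovery: can calibration find the generating truth?

    Generates a zero-noise subject, calibrates the fused model in
    inter-speed mode, and reports per-muscle errors of the allocation gain
    (absolute) and maximal force (percent), plus held-out prediction R^2
    with both the recovered and the true parameters.
    """
    constants = constants or default_constants()
    cfg = SyntheticConfig(seed=seed, noise=ZERO_NOISE)
    data = forward_generate(cfg, constants)
    model = HillModel(constants, ActivationFilterParams(),
                      SignalConfig(fs_model=cfg.fs_model))
    preps = prepare_all(data, model)
    ds = build_dataset(preps, "inter", seed=seed)
    result = calibrate(ds, "fused", constants, model, optimizer)

    truth = cfg.true_params
    out = {"seed": seed, "objective": result.objective, "converged": result.converged}
    for m in MUSCLES:
        fit_p, true_p = result.params.muscle(m), truth.muscle(m)
        out[f"delta_err_{m}"] = abs(fit_p.delta - true_p.delta)
        out[f"fmax_err_pct_{m}"] = 100.0 * abs(fit_p.Fmax - true_p.Fmax) / true_p.Fmax
    peak = peak_moment(preps)
    for label, params in (("fit", result.params), ("true", truth)):
        preds, truths = [], []
        for b in ds.held_out:
            preds.append(predict(b.prep, params, [b.cycle], model)[0].values)
            truths.append(b.target)
        mb = metrics(np.concatenate(preds), np.concatenate(truths), peak, cfg.body_mass)
        out[f"r2_{label}"] = mb.r2
        out[f"n_rmse_{label}"] = mb.n_rmse
    return out
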