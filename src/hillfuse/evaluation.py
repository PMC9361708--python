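"""Accuracy metrics, feature-moment correlation analysis and variant comparison.

Prediction quality is summarized by RMSE in N*m plus two normalizations that
make subjects comparable — N-RMSE (percent of the individual peak net
plantarflexion moment) and BM-RMSE (per kilogram of body mass) — and the
coefficient of determination R^2 about the benchmark mean.  The correlation
analysis computes per-stance-cycle Pearson correlations between each
neuromuscular feature (sEMG envelope, muscle thickness; both muscles) and
the benchmark moment, aggregated through the Fisher z-transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .model import PreparedTrial
from .trial import MUSCLES

log = logging.getLogger(__name__)

__all__ = ["MetricBundle", "metrics", "peak_moment", "correlation_table", "compare_variants"]

FEATURES = tuple(f"{m}_{kind}" for kind in ("semg", "mt") for m in MUSCLES)


@dataclass(frozen=True)
class MetricBundle:
    """One prediction-vs-benchmark comparison."""

    rmse: float  # N*m
    n_rmse: float  # percent of individual peak moment
    bm_rmse: float  # N*m per kg body mass
    r2: float


def metrics(pred: np.ndarray, truth: np.ndarray, peak_moment: float,
            body_mass: float) -> MetricBundle:
    """RMSE, N-RMSE (%), BM-RMSE (N*m/kg) and R^2 of a prediction.

    R^2 = 1 - SS_res/SS_tot about the mean of the benchmark series; a
    constant benchmark leaves it undefined and raises.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 2:
        raise DataError("pred and truth must share a length of at least 2")
    if peak_moment <= 0 or body_mass <= 0:
        raise DataError("peak moment and body mass must be positive")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("benchmark series has zero variance; R^2 undefined")
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    r2 = 1.0 - float(np.sum((pred - truth) ** 2)) / ss_tot
    return MetricBundle(
        rmse=rmse,
        n_rmse=100.0 * rmse / peak_moment,
        bm_rmse=rmse / body_mass,
        r2=r2,
    )


def peak_moment(preps: list[PreparedTrial]) -> float:
    """Individual peak net plantarflexion moment.

    The subject-constant normalizer for N-RMSE: the maximum benchmark moment
    over the stance samples of all retained cycles of all speeds.
    """
    peak = 0.0
    for p in preps:
        if p.moment is None:
            continue
        for cyc in p.stance:
            peak = max(peak, float(np.max(p.moment[cyc.slice()])))
    if peak <= 0:
        raise DataError("no positive benchmark moment found")
    return peak


def correlation_table(preps: list[PreparedTrial]) -> pd.DataFrame:
    """Per-cycle feature-moment Pearson correlations, Fisher-aggregated.

    For every stance cycle, the Pearson r between each feature series
    (normalized sEMG envelope and thickness-derived activation, per muscle)
    and the benchmark moment over that cycle.  r is clipped to +/-(1-1e-9),
    z = arctanh(r); the table reports the tanh-back-transformed z-mean per
    (feature, speed) and both the z-space and r-space SDs (the aggregation
    space is stated explicitly because reporting conventions differ).
    Cycles with a constant series are skipped with a log message.
    """
    rows = []
    for p in preps:
        if p.moment is None:
            raise DataError("correlation analysis needs the benchmark moment channel")
        feats = {f"{m}_semg": p.N[m] for m in MUSCLES} | {f"{m}_mt": p.a2[m] for m in MUSCLES}
        for ci, cyc in enumerate(p.stance):
            mom = p.moment[cyc.slice()]
            if np.ptp(mom) == 0:
                log.warning("constant moment in cycle %d at %.2f m/s; skipped", ci, p.speed)
                continue
            for name, series in feats.items():
                x = series[cyc.slice()]
                if np.ptp(x) == 0:
                    log.warning("constant %s in cycle %d at %.2f m/s; skipped", name, ci, p.speed)
                    continue
                r = float(stats.pearsonr(x, mom).statistic)
                r = float(np.clip(r, -(1 - 1e-9), 1 - 1e-9))
                rows.append({"feature": name, "speed": p.speed, "cycle": ci,
                             "r": r, "z": float(np.arctanh(r))})
    if not rows:
        return pd.DataFrame(columns=["feature", "speed", "mean_r", "sd_z", "sd_r", "n_cycles"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["feature", "speed"])
        .agg(mean_z=("z", "mean"), sd_z=("z", "std"), sd_r=("r", "std"), n_cycles=("r", "size"))
        .reset_index()
    )
    out["mean_r"] = np.tanh(out.pop("mean_z"))
    return out[["feature", "speed", "mean_r", "sd_z", "sd_r", "n_cycles"]]


def compare_variants(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive comparison of HNM variants across calibration modes and speeds.

    ``table`` is tidy with columns (variant, mode, speed, rmse, n_rmse,
    bm_rmse, r2), one row per prediction cell.  Returns per (variant, mode)
    means, the percent change of mean N-RMSE relative to the sEMG-only and
    ultrasound-only variants within the same mode, and the across-speed SD
    of N-RMSE (a robustness proxy).  Missing cells simply propagate NaN.
    """
    needed = {"variant", "mode", "speed", "n_rmse"}
    if not needed <= set(table.columns):
        raise DataError(f"comparison table needs columns {sorted(needed)}")
    value_cols = [c for c in ("rmse", "n_rmse", "bm_rmse", "r2") if c in table.columns]
    grouped = table.groupby(["variant", "mode"])[value_cols].mean().reset_index()
    spread = (
        table.groupby(["variant", "mode", "speed"])["n_rmse"].mean()
        .groupby(["variant", "mode"]).std()
        .rename("n_rmse_across_speed_sd").reset_index()
    )
    out = grouped.merge(spread, on=["variant", "mode"], how="left")

    for ref in ("semg_only", "us_only"):
        ref_vals = out[out["variant"] == ref].set_index("mode")["n_rmse"]
        out[f"n_rmse_change_vs_{ref}_pct"] = [
            100.0 * (row.n_rmse - ref_vals[row.mode]) / ref_vals[row.mode]
            if row.mode in ref_vals.index else np.nan
            for row in out.itertuples()
        ]
    return out
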