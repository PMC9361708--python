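"""Reading and writing trials, manifests and result files.

A trial is a delimited table with a fixed header
(``time, angle_rad, grf_v_N, semg_lgs, semg_sol, mt_lgs_mm, mt_sol_mm,
moment_Nm``) at a uniform rate; trial-level metadata (speed, body mass)
lives in a ``manifest.json`` next to the per-speed CSV files.  Calibration
results are written as JSON with the parameter boxes and provenance; metric
tables as tidy CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .errors import DataError, SchemaError
from .musculotendon import HnmParameters, MuscleParams
from .signals import UniformSeries
from .synthetic import SyntheticDataset
from .trial import CHANNEL_NAMES, MANDATORY_CHANNELS, GaitTrial

log = logging.getLogger(__name__)

__all__ = [
    "read_trial",
    "write_trial",
    "read_trials",
    "write_dataset",
    "write_result",
    "read_result",
    "write_metrics",
]

SCHEMA_VERSION = 1

_UNITS = {
    "angle_rad": "rad", "grf_v_N": "N", "semg_lgs": "norm", "semg_sol": "norm",
    "mt_lgs_mm": "mm", "mt_sol_mm": "mm", "moment_Nm": "N*m",
}


def read_trial(path: str | Path, speed: float, body_mass: float) -> GaitTrial:
    """Read one trial CSV; the time column defines the (uniform) grid.

    Missing mandatory columns raise a schema error naming the column;
    unknown extra columns are ignored with a warning; a missing benchmark
    moment column is tolerated (prediction-only input).
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'time'")
    for col in MANDATORY_CHANNELS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    extra = set(df.columns) - {"time", *CHANNEL_NAMES}
    if extra:
        log.warning("%s: ignoring unknown columns %s", path, sorted(extra))

    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise DataError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / float(steps[0])

    channels = {
        col: UniformSeries(float(t[0]), fs, df[col].to_numpy(dtype=float), _UNITS[col])
        for col in CHANNEL_NAMES
        if col in df.columns
    }
    return GaitTrial(speed=speed, body_mass=body_mass, channels=channels,
                     provenance={"source": str(path)})


def write_trial(trial: GaitTrial, path: str | Path) -> Path:
    """Write a trial to CSV with the fixed header contract."""
    path = Path(path)
    first = next(iter(trial.channels.values()))
    data = {"time": first.time()}
    for col in CHANNEL_NAMES:
        if col in trial.channels:
            data[col] = trial.channels[col].values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    return path


def write_dataset(data: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a generated dataset: one CSV per speed plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in data.trials:
        name = f"trial_{trial.speed:.2f}ms.csv"
        write_trial(trial, out / name)
        entries.append({"file": name, "speed": trial.speed,
                        "body_mass": trial.body_mass})
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "generator_digest": data.config.digest(),
        "seed": data.config.seed,
        "trials": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_trials(in_dir: str | Path) -> list[GaitTrial]:
    """Read every trial listed in a directory's manifest."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    return [
        read_trial(in_dir / e["file"], speed=e["speed"], body_mass=e["body_mass"])
        for e in manifest["trials"]
    ]


def write_result(result: CalibrationResult, path: str | Path) -> Path:
    """Serialize a calibration result to JSON (round-trips via read_result)."""
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION, **dataclasses.asdict(result)}
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_result(path: str | Path) -> CalibrationResult:
    raw = json.loads(Path(path).read_text())
    raw.pop("schema_version", None)
    raw["params"] = HnmParameters(
        lgs=MuscleParams(**raw["params"]["lgs"]),
        sol=MuscleParams(**raw["params"]["sol"]),
    )
    return CalibrationResult(**raw)


def write_metrics(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy metrics table as CSV (header always present, even if empty)."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path
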