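"""Shared fixtures: muscle constants, synthetic datasets and the (expensive)
multi-seed benchmark, computed once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from hillfuse.activation import ActivationFilterParams
from hillfuse.benchmark import prepare_all, recovery_experiment, run_study
from hillfuse.config import SignalConfig, ZERO_NOISE
from hillfuse.model import HillModel
from hillfuse.musculotendon import default_constants
from hillfuse.synthetic import SyntheticConfig, forward_generate

BENCH_SEEDS = range(1, 11)
RECOVERY_SEEDS = range(1, 6)


@pytest.fixture(scope="session")
def constants():
    return default_constants()


@pytest.fixture(scope="session")
def model(constants):
    return HillModel(constants, ActivationFilterParams(), SignalConfig())


@pytest.fixture(scope="session")
def clean_dataset(constants):
    """Zero-noise synthetic dataset (seed 1): exact model consistency holds."""
    return forward_generate(SyntheticConfig(seed=1, noise=ZERO_NOISE), constants)


@pytest.fixture(scope="session")
def noisy_dataset(constants):
    """Default (moderate) noise synthetic dataset, seed 1."""
    return forward_generate(SyntheticConfig(seed=1), constants)


@pytest.fixture(scope="session")
def clean_preps(clean_dataset, model):
    return prepare_all(clean_dataset, model)


@pytest.fixture(scope="session")
def noisy_preps(noisy_dataset, model):
    return prepare_all(noisy_dataset, model)


@pytest.fixture(scope="session")
def recovery_runs():
    """Noise-free parameter recovery across the standard seed set."""
    return [recovery_experiment(seed) for seed in RECOVERY_SEEDS]


@pytest.fixture(scope="session")
def benchmark_df() -> pd.DataFrame:
    """Held-out metrics of the complementary-noise benchmark, 10 seeds.

    Inter-speed calibration for all four variants plus single-speed (0.50
    m/s) calibration for the fused variant; tidy rows (variant, mode, speed,
    seed, metrics).
    """
    rows = []
    for seed in BENCH_SEEDS:
        inter = run_study(
            seed,
            variants=("fused", "semg_only", "us_only", "random_signal"),
            modes=("inter",),
        )
        single = run_study(seed, variants=("fused",), modes=("single:0.5",))
        for t in (inter.table, single.table):
            t = t.copy()
            t["seed"] = seed
            rows.append(t)
    return pd.concat(rows, ignore_index=True)
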