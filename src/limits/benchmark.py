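"""Synthetic benchmarks of inference quality.

Two sweeps, mirroring the standard evaluation of timeseries network
inference:

* :func:`parameter_recovery_benchmark` — how well the coefficient *values*
  are recovered from noiseless measurements (process noise only), on both
  absolute and relative abundances, as squared Pearson correlation between
  true and inferred matrices.
* :func:`noise_robustness_benchmark` — how well the network *topology*
  (which pairs interact) survives multiplicative measurement noise, as
  per-matrix sensitivity and specificity across noise levels and
  acceptance thresholds, with and without median bagging.

Both return tidy long-format DataFrames, one row per (matrix, condition).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .dlv_sim import (
    GeneratorParams,
    NoiseSpec,
    add_measurement_noise,
    generate_random_interactions,
    simulate,
    to_relative,
)
from .limits_core import LimitsConfig, limits_infer
from .network_eval import recovery_r2, topology_metrics

__all__ = [
    "make_benchmark_community",
    "parameter_recovery_benchmark",
    "noise_robustness_benchmark",
]

# Benchmark defaults: 10-species sparse communities observed for 500 steps
# from 10 independent initial conditions with process noise sigma = 0.05.
N_SPECIES = 10
N_TIMESTEPS = 500
N_REPLICATES = 10
SIGMA_PROCESS = 0.05


def make_benchmark_community(
    seed: int,
    n_species: int = N_SPECIES,
    n_timesteps: int = N_TIMESTEPS,
    n_replicates: int = N_REPLICATES,
    sigma_process: float = SIGMA_PROCESS,
    params: GeneratorParams | None = None,
):
    """One random stable community and its simulated absolute timeseries."""
    rng = np.random.default_rng(seed)
    model = generate_random_interactions(n_species, seed=rng, params=params)
    ts = simulate(
        model,
        T=n_timesteps,
        R=n_replicates,
        noise=NoiseSpec(sigma_process=sigma_process),
        seed=rng,
    )
    return model, ts


def parameter_recovery_benchmark(
    n_matrices: int = 10,
    threshold: float = 0.05,
    n_bootstrap: int = 50,
    seed: int = 0,
    n_timesteps: int = N_TIMESTEPS,
    n_replicates: int = N_REPLICATES,
) -> pd.DataFrame:
    """Coefficient recovery from noiseless measurements.

    For each random community, LIMITS is run on the absolute abundances and
    on their relative (compositional) version; the score is the squared
    Pearson correlation between vectorized true and inferred coefficients.
    Columns: matrix, kind, r_squared, scale.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_matrices) % (2**31)
    rows = []
    for k in range(n_matrices):
        model, ts_abs = make_benchmark_community(
            int(seeds[k]), n_timesteps=n_timesteps, n_replicates=n_replicates
        )
        for kind, ts in (("absolute", ts_abs), ("relative", to_relative(ts_abs))):
            config = LimitsConfig(
                threshold=threshold, n_bootstrap=n_bootstrap, seed=int(seeds[k])
            )
            net = limits_infer(ts, config)
            score = recovery_r2(model, net)
            rows.append(
                {
                    "matrix": k,
                    "kind": kind,
                    "r_squared": score.r_squared,
                    "scale": score.scale,
                }
            )
    return pd.DataFrame(rows)


def noise_robustness_benchmark(
    n_matrices: int = 10,
    noise_levels: Sequence[float] = (0.0, 0.05, 0.10),
    thresholds: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.05),
    n_bootstrap: int = 50,
    bagged: bool = True,
    seed: int = 0,
    n_timesteps: int = N_TIMESTEPS,
    n_replicates: int = N_REPLICATES,
) -> pd.DataFrame:
    """Topology recovery from noisy relative abundances.

    Each community's relative abundances are corrupted with multiplicative
    log-normal measurement noise at the given levels, LIMITS is run at each
    acceptance threshold (bagged by the median, or unbagged: a single
    stepwise fit on all the data), and sensitivity / specificity are scored
    against the true topology.  Columns: matrix, noise, threshold, bagged,
    sensitivity, specificity, sign_error_rate.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_matrices) % (2**31)
    rows = []
    for k in range(n_matrices):
        model, ts_abs = make_benchmark_community(
            int(seeds[k]), n_timesteps=n_timesteps, n_replicates=n_replicates
        )
        ts_rel = to_relative(ts_abs)
        for noise in noise_levels:
            observed = add_measurement_noise(ts_rel, noise, seed=int(seeds[k]) + 1)
            for threshold in thresholds:
                config = LimitsConfig(
                    threshold=threshold,
                    n_bootstrap=n_bootstrap,
                    seed=int(seeds[k]),
                    bagged=bagged,
                )
                net = limits_infer(observed, config)
                metrics = topology_metrics(model, net)
                rows.append(
                    {
                        "matrix": k,
                        "noise": noise,
                        "threshold": threshold,
                        "bagged": bagged,
                        "sensitivity": metrics.sensitivity,
                        "specificity": metrics.specificity,
                        "sign_error_rate": metrics.sign_error_rate,
                    }
                )
    return pd.DataFrame(rows)
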