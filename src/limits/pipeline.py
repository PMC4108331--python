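"""End-to-end workflows with on-disk artifacts and a run manifest.

`run_pipeline` wires the stages (simulate -> infer -> evaluate, or
table -> top-taxa selection -> infer -> keystone ranking) from a single
config mapping and records a JSON manifest with the exact configuration,
seed, package version and input checksums, so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .dlv_sim import (
    GeneratorParams,
    NoiseSpec,
    add_measurement_noise,
    generate_random_interactions,
    simulate,
    to_relative,
)
from .limits_core import LimitsConfig, limits_infer
from .network_eval import out_degree_ranking, recovery_r2, topology_metrics
from . import io as lio

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: dict, inputs: list[Path]) -> None:
    manifest = {
        "config": config,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "input_checksums": {str(p): _checksum(p) for p in inputs if p.exists()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_pipeline(config: dict) -> dict:
    """Run a configured workflow; returns a summary dict of artifact paths.

    Config keys (with defaults):

    mode
        ``"synthetic"`` — generate a random community, simulate, infer and
        evaluate against the known truth; or ``"infer"`` — read an abundance
        table (optionally pre-select top taxa) and infer its network.
    outdir
        Output directory (created if needed).
    seed
        Controls every stochastic stage.
    Simulation keys: n_species, n_offdiag, n_timesteps, n_replicates,
    sigma_process, sigma_measurement, relative (bool).
    Inference keys: threshold, n_bootstrap, bagged, top_n, input (for
    mode="infer"), kind ("absolute"/"relative").
    """
    cfg = dict(config)
    mode = cfg.setdefault("mode", "synthetic")
    outdir = Path(cfg.get("outdir", "limits_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.setdefault("seed", 0))
    threshold = float(cfg.setdefault("threshold", 0.03))
    n_bootstrap = int(cfg.setdefault("n_bootstrap", 100))
    bagged = bool(cfg.setdefault("bagged", True))
    summary: dict = {"outdir": str(outdir)}
    inputs: list[Path] = []

    if mode == "synthetic":
        try:
            model = generate_random_interactions(
                int(cfg.setdefault("n_species", 10)),
                cfg.get("n_offdiag"),
                seed=seed,
                params=GeneratorParams(),
            )
            ts = simulate(
                model,
                T=int(cfg.setdefault("n_timesteps", 500)),
                R=int(cfg.setdefault("n_replicates", 10)),
                noise=NoiseSpec(sigma_process=float(cfg.setdefault("sigma_process", 0.05))),
                seed=seed + 1,
            )
            if cfg.setdefault("relative", False):
                ts = to_relative(ts)
            sigma_meas = float(cfg.setdefault("sigma_measurement", 0.0))
            if sigma_meas > 0:
                ts = add_measurement_noise(ts, sigma_meas, seed=seed + 2)
        except Exception as exc:
            raise PipelineError(f"simulate stage failed: {exc}") from exc
        lio.write_abundance_table(ts, outdir / "abundance.tsv", provenance=cfg)
        lio.write_edge_list(model, outdir / "true_edges.tsv")
        lio.write_equilibrium(model, outdir / "equilibrium.tsv")
        summary["abundance"] = str(outdir / "abundance.tsv")
    elif mode == "infer":
        try:
            ts = lio.read_abundance_table(Path(cfg["input"]), kind=cfg.get("kind"))
            inputs.append(Path(cfg["input"]))
        except KeyError as exc:
            raise PipelineError("infer stage failed: config key 'input' required") from exc
        except Exception as exc:
            raise PipelineError(f"read stage failed: {exc}") from exc
        model = None
        top_n = cfg.get("top_n")
        if top_n:
            keep = lio.select_top_taxa([ts], int(top_n))
            idx = [ts.labels.index(label) for label in keep]
            values = ts.values[idx]
            if ts.kind == "relative":  # re-close the composition on the subset
                values = values / values.sum(axis=0, keepdims=True)
            ts = type(ts)(values=values, kind=ts.kind, dt=ts.dt, labels=keep)
    else:
        raise PipelineError(f"unknown pipeline mode {mode!r}")

    try:
        net = limits_infer(
            ts,
            LimitsConfig(
                threshold=threshold, n_bootstrap=n_bootstrap, seed=seed, bagged=bagged
            ),
        )
    except Exception as exc:
        raise PipelineError(f"infer stage failed: {exc}") from exc

    lio.write_edge_list(net, outdir / "inferred_edges.tsv")
    lio.write_graphml(net, outdir / "inferred_network.graphml")
    summary["inferred_edges"] = str(outdir / "inferred_edges.tsv")

    ranking, median_degree = out_degree_ranking(net)
    summary["keystone_ranking"] = ranking
    summary["median_out_degree"] = median_degree
    (outdir / "keystones.json").write_text(
        json.dumps(
            {"ranking": ranking, "median_out_degree": median_degree}, indent=2
        )
        + "\n"
    )

    if mode == "synthetic":
        try:
            metrics = topology_metrics(model, net)
            score = recovery_r2(model, net)
        except Exception as exc:
            raise PipelineError(f"evaluate stage failed: {exc}") from exc
        evaluation = {**asdict(metrics), "r_squared": score.r_squared, "scale": score.scale}
        (outdir / "metrics.json").write_text(json.dumps(evaluation, indent=2) + "\n")
        summary["metrics"] = evaluation

    _write_manifest(outdir, cfg, inputs)
    summary["manifest"] = str(outdir / "manifest.json")
    return summary
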