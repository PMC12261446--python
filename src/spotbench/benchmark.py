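"""Benchmark orchestration: simulate -> select features -> deconvolve -> evaluate.

A run is declared in a YAML configuration:

.. code-block:: yaml

    seed: 0
    outdir: runs/demo
    reference:
      synthetic: {n_cells: 1200, n_genes: 600, n_peaks: 900, n_cell_types: 6}
    simulations:
      - {name: hb1, n_spots: 200, zonation: uniform, mean_cell_types: 3, mean_cells: 5}
    features:
      - {modality: atac, strategy: highly_variable_peaks, n: 300}
    methods: [majority_oracle, nnls]
    metrics: {rare_types: [], threshold: 0.05}

Every dataset x feature-strategy x method cell is executed, per-cell
predicted proportions are written as TSVs, and a combined report (rows plus
mean +- sd aggregates) is produced; the whole run is a pure function of
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baselines import majority_baseline, nnls_deconvolve
from .datasets import ReferenceDataset
from .features import select_features
from .io import _write_tsv, read_reference_bundle, write_proportions_tsv
from .metrics import MetricReport, evaluate
from .silver import SimulationConfig, simulate_spots
from .synthetic import ReferenceConfig, generate_reference

logger = logging.getLogger(__name__)

__all__ = ["load_run_config", "run_benchmark"]

_KNOWN_METHODS = ("majority_oracle", "majority_global", "nnls")


def load_run_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_run_config(config)
    return config


def validate_run_config(config: dict) -> None:
    """Fail fast: every referenced path and block must resolve before execution."""
    for key in ("reference", "simulations", "features", "methods"):
        if key not in config:
            raise ValueError(f"run config is missing the {key!r} block")
    ref = config["reference"]
    if "path" in ref:
        if not Path(ref["path"]).exists():
            raise FileNotFoundError(f"reference path does not exist: {ref['path']}")
    elif "synthetic" not in ref:
        raise ValueError("reference block needs either 'path' or 'synthetic'")
    for sim in config["simulations"]:
        if "name" not in sim:
            raise ValueError("every simulation block needs a 'name'")
        SimulationConfig(**{k: v for k, v in sim.items() if k != "name"})
    for feat in config["features"]:
        for key in ("modality", "strategy", "n"):
            if key not in feat:
                raise ValueError(f"feature block missing {key!r}: {feat}")
    for method in config["methods"]:
        if method not in _KNOWN_METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {_KNOWN_METHODS}")


def _load_reference(block: dict, seed: int) -> ReferenceDataset:
    if "path" in block:
        return read_reference_bundle(block["path"])
    return generate_reference(ReferenceConfig(**{**block["synthetic"], "seed": seed}))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_benchmark(config: dict, outdir=None) -> MetricReport:
    """Execute all benchmark cells and write proportion TSVs plus report.tsv."""
    validate_run_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "benchmark_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("spotbench %s | seed=%d | config hash %s", __version__, seed,
                _config_hash(config))

    reference = _load_reference(config["reference"], seed)
    metric_opts = config.get("metrics", {})
    rare_types = metric_opts.get("rare_types", [])
    threshold = float(metric_opts.get("threshold", 0.05))

    report = MetricReport()
    for sim_block in config["simulations"]:
        sim_name = sim_block["name"]
        sim_cfg = SimulationConfig(**{**{k: v for k, v in sim_block.items() if k != "name"},
                                      "seed": seed})
        spots = simulate_spots(reference, sim_cfg)
        for feat_block in config["features"]:
            selection = select_features(reference, feat_block["modality"],
                                        feat_block["strategy"], int(feat_block["n"]))
            for method in config["methods"]:
                cell = f"{sim_name}.{feat_block['strategy']}.{method}"
                try:
                    result = _run_method(method, reference, spots, selection)
                except Exception as err:
                    raise RuntimeError(f"benchmark cell {cell!r} failed") from err
                write_proportions_tsv(result.proportions,
                                      outdir / f"proportions_{cell}.tsv",
                                      spot_names=spots.spot_names)
                row = evaluate(spots.true_proportions, result.proportions,
                               rare_types=rare_types, threshold=threshold,
                               dataset=sim_name, method=method,
                               modality=feat_block["modality"],
                               strategy=feat_block["strategy"])
                report.add(row)

    _write_tsv(outdir / "report.tsv", report.rows)
    _write_tsv(outdir / "report_aggregate.tsv", report.aggregate())
    return report


def _run_method(method: str, reference, spots, selection):
    if method == "majority_oracle":
        return majority_baseline(true=spots.true_proportions, mode="oracle_spot")
    if method == "majority_global":
        return majority_baseline(true=spots.true_proportions, mode="global_reference",
                                 reference_labels=reference.cell_types)
    if method == "nnls":
        return nnls_deconvolve(reference, spots, selection)
    raise ValueError(f"unknown method {method!r}")
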