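"""End-to-end orchestration: files → fitted model → proportion tables,
benchmark repetition over seeds, and fixture generation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, simulate
from .config import RunConfig
from .model import SpatialDeconvolutionModel

__all__ = ["run_deconvolution", "run_benchmark", "make_fixture"]


def run_deconvolution(st_path, sc_path, out_dir, annotation_key: str = "cell_type",
                      config: RunConfig | None = None,
                      st_format: str | None = None, sc_format: str | None = None):
    """Load inputs, fit the model and write all artifacts to ``out_dir``."""
    config = config or RunConfig()
    model = SpatialDeconvolutionModel.from_files(
        st_path, sc_path, annotation_key=annotation_key, config=config,
        st_format=st_format, sc_format=sc_format)
    result = model.fit()
    result.save(out_dir)
    return result


def run_benchmark(fixture_dir, out_dir=None, config: RunConfig | None = None,
                  n_repeats: int = 10, post_filter: bool = True):
    """Repeat a full deconvolution over seeds on a fixture with ground truth.

    The fixture directory is the layout written by
    :func:`spotcycle.simulate.write_fixture`. Returns
    ``(per_repeat_table, summary_dict)`` and, when ``out_dir`` is given,
    writes ``benchmark.csv`` / ``benchmark_summary.json``.
    """
    fixture_dir = Path(fixture_dir)
    config = config or RunConfig()
    with open(fixture_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    truth = pd.read_csv(fixture_dir / manifest["ground_truth"], index_col=0)
    model = SpatialDeconvolutionModel.from_files(
        fixture_dir / manifest["st"], fixture_dir / manifest["sc"],
        annotation_key=manifest.get("annotation_key", "cell_type"),
        config=config)

    def run(seed):
        res = model.fit(seed=seed)
        s = res.score(truth, post_filter=post_filter)
        return s["rmse"], s["jsd"]

    seeds = [config.seed + i for i in range(n_repeats)]
    table, summary = metrics.evaluate_repeated(run, n_repeats=n_repeats,
                                               seeds=seeds)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "benchmark.csv", index=False)
        with open(out / "benchmark_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        config.to_yaml(out / "config.yaml")
    return table, summary


def make_fixture(out_dir, preset: str = "small", seed: int | None = None,
                 **overrides):
    """Write a synthetic paired fixture for one of the named presets."""
    if preset not in simulate.PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(simulate.PRESETS)}")
    base = simulate.PRESETS[preset]
    d = {**base.__dict__, **overrides}
    if seed is not None:
        d["seed"] = int(seed)
    cfg = simulate.SimulationConfig(**d)
    ref, st, gt = simulate.simulate_pair(cfg)
    return simulate.write_fixture(ref, st, gt, out_dir, config=cfg)
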