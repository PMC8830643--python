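"""The end-to-end study pipeline: design -> simulate -> fit -> analyze.

A :class:`PipelineConfig` describes the whole experiment: the parameter
space, the demographic configuration, the design method and batch sizes
(default 200, 400, 800 and 1600 runs — 3000 simulator executions in
total), the surrogate roster and the seeds.  :func:`run_pipeline` executes
it batch by batch, writing a design CSV, a run-table CSV, a surrogate
leaderboard and the PCA/scree outputs per batch, plus a manifest recording
every seed and row count.

Batches are generated independently: each takes a disjoint segment of the
Sobol sequence (or a fresh LHD seed), so no two runs anywhere in the study
share a parameter vector.  Per-run seeds expand deterministically from the
base seed as ``base + global_row_index``, making every batch reproducible
and extendable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .abm.config import DemographyConfig
from .abm.engine import batch_run
from .analysis import pca_with_retention, zscore
from .design import lptau_design, maximin_lhd, write_design
from .errors import InvalidConfigError
from .io import write_runs
from .space import Parameter, ParameterSpace, default_space
from .surrogates import METHODS, SurrogateSpec, benchmark_all

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_SIZES = (200, 400, 800, 1600)


@dataclass
class PipelineConfig:
    """Everything needed to run the full study."""

    space: ParameterSpace = field(default_factory=default_space)
    demography: DemographyConfig = field(default_factory=DemographyConfig)
    design_method: str = "lptau"
    sizes: tuple = DEFAULT_SIZES
    base_seed: int = 0
    split_seed: int = 0
    roster: tuple = METHODS
    hyperparameters: dict = field(default_factory=dict)  # method -> overrides
    pca_include_output: bool = True

    def __post_init__(self):
        if self.design_method not in ("lptau", "lhd"):
            raise InvalidConfigError(
                f"design_method must be 'lptau' or 'lhd', got {self.design_method!r}"
            )
        self.sizes = tuple(int(s) for s in self.sizes)
        if any(s <= 0 for s in self.sizes):
            raise InvalidConfigError("batch sizes must be positive")
        self.roster = tuple(self.roster)
        unknown = set(self.roster) - set(METHODS)
        if unknown:
            raise InvalidConfigError(f"unknown surrogate methods: {sorted(unknown)}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "ranges": {
                p.name: [p.lower, p.upper] for p in self.space.parameters
            },
            "demography": self.demography.to_dict(),
            "design_method": self.design_method,
            "sizes": list(self.sizes),
            "base_seed": self.base_seed,
            "split_seed": self.split_seed,
            "roster": list(self.roster),
            "hyperparameters": self.hyperparameters,
            "pca_include_output": self.pca_include_output,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        known = {
            "ranges", "demography", "design_method", "sizes", "base_seed",
            "split_seed", "roster", "hyperparameters", "pca_include_output",
        }
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "ranges" in d:
            base = default_space()
            params = []
            offenders = []
            ranges = dict(d["ranges"])
            for p in base.parameters:
                if p.name in ranges:
                    lo, hi = ranges.pop(p.name)
                    if not lo < hi:
                        offenders.append(f"{p.name}: ({lo}, {hi})")
                        continue
                    params.append(Parameter(p.name, lo, hi, p.default, p.integer))
                else:
                    params.append(p)
            if ranges:
                offenders.extend(f"unknown parameter {n!r}" for n in ranges)
            if offenders:
                raise InvalidConfigError(
                    "invalid parameter ranges: " + "; ".join(offenders)
                )
            kwargs["space"] = ParameterSpace(tuple(params))
        if "demography" in d:
            kwargs["demography"] = DemographyConfig.from_dict(d["demography"])
        for key in ("design_method", "sizes", "base_seed", "split_seed",
                    "roster", "hyperparameters", "pca_include_output"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON; empty file -> all defaults."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        d = json.loads(text) if text.strip() else {}
    else:
        d = yaml.safe_load(text) or {}
    if not isinstance(d, dict):
        raise InvalidConfigError(f"config root must be a mapping, got {type(d)}")
    return PipelineConfig.from_dict(d)


def _make_design(config: PipelineConfig, n: int, offset: int):
    if config.design_method == "lptau":
        return lptau_design(n, config.space, skip=1 + offset)
    return maximin_lhd(n, config.space, seed=config.base_seed + offset)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured study; returns the manifest (also written).

    Per batch: ``design_<n>.csv``, ``runs_<n>.csv``, ``leaderboard_<n>.json``
    / ``.csv`` and ``pca_<n>.json``.  The manifest records every seed, row
    counts and per-stage timings; any stage failure aborts with the
    manifest of completed stages on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "batches": [],
        "total_runs": 0,
    }
    manifest_path = outdir / "manifest.json"
    offset = 0
    try:
        for n in config.sizes:
            entry = {"n": n, "stages": {}}
            t0 = time.perf_counter()
            design = _make_design(config, n, offset)
            write_design(design, outdir / f"design_{n}.csv")
            entry["stages"]["design"] = time.perf_counter() - t0
            log.info("batch %d: design done (%.2fs)", n, entry["stages"]["design"])

            t0 = time.perf_counter()
            seeds = [config.base_seed + offset + i for i in range(n)]
            runs = batch_run(design, config.demography, seeds)
            write_runs(runs, outdir / f"runs_{n}.csv")
            entry["stages"]["simulate"] = time.perf_counter() - t0
            entry["seeds"] = [seeds[0], seeds[-1]]
            entry["rows"] = len(runs)
            log.info("batch %d: %d runs done (%.2fs)", n, len(runs),
                     entry["stages"]["simulate"])

            if config.roster:
                t0 = time.perf_counter()
                specs = [
                    SurrogateSpec(m, dict(config.hyperparameters.get(m, {})),
                                  seed=config.base_seed)
                    for m in config.roster
                ]
                board = benchmark_all(runs, specs, config.split_seed)
                records = board.as_records()
                (outdir / f"leaderboard_{n}.json").write_text(
                    json.dumps(records, indent=2, default=str)
                )
                pd.DataFrame(records).to_csv(
                    outdir / f"leaderboard_{n}.csv", index=False
                )
                entry["stages"]["fit"] = time.perf_counter() - t0
                log.info("batch %d: surrogates done (%.2fs)", n,
                         entry["stages"]["fit"])

            t0 = time.perf_counter()
            frame = runs.frame[
                list(config.space.names) + (["output"] if config.pca_include_output else [])
            ]
            pca = pca_with_retention(zscore(frame))
            (outdir / f"pca_{n}.json").write_text(json.dumps({
                "eigenvalues": pca.eigenvalues.tolist(),
                "explained_pct": pca.explained_pct.tolist(),
                "retained": pca.retained,
                "significant": [list(map(str, s)) for s in pca.significant],
            }, indent=2))
            entry["stages"]["analyze"] = time.perf_counter() - t0

            manifest["batches"].append(entry)
            manifest["total_runs"] += entry["rows"]
            offset += n
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
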