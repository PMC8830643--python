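"""Run-table and configuration file I/O.

Run tables are CSV with the canonical 12-column schema (ten parameters,
the seed, the output), UTF-8, '.' decimal, written at full ``repr``
precision so that a read of a write reproduces the table exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .abm.config import DemographyConfig
from .abm.engine import RUN_COLUMNS, RunTable
from .errors import SchemaError

__all__ = ["read_runs", "write_runs", "load_demography", "save_demography"]


def write_runs(table: RunTable, path) -> None:
    """Write a run table as CSV (lossless at full printed precision)."""
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_runs(path) -> RunTable:
    """Read a run-table CSV, enforcing the canonical schema.

    The mandatory ``seed`` column preserves the determinism contract: any
    stored run can be reproduced exactly from its row.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(RUN_COLUMNS) - set(frame.columns)
    if missing or tuple(frame.columns) != RUN_COLUMNS:
        raise SchemaError(
            f"run table columns must be {list(RUN_COLUMNS)}, got {list(frame.columns)}"
        )
    float_cols = [c for c in RUN_COLUMNS if c != "seed"]
    frame[float_cols] = frame[float_cols].astype(float)
    frame["seed"] = frame["seed"].astype(int)
    return RunTable(frame)


def save_demography(config: DemographyConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_demography(path) -> DemographyConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return DemographyConfig.from_dict(d or {})
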