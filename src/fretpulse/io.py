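"""Delimited-text readers/writers, schema validation, and run configuration.

All tables are plain comma-separated text with a header row.  Trace times
are minutes (``time_min``, t = 0 at the perturbation); growth curves use
hours (``time_h``).  Every pipeline output directory receives an echo of
the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import GrowthCurve

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["cell_id", "frame", "time_min", "donor", "acceptor"]
FLOW_COLUMNS = ["fsc", "ssc", "donor_ch", "fret_ch", "direct_acceptor_ch"]

__all__ = [
    "RunConfig",
    "read_trace_table",
    "write_trace_table",
    "read_flow_table",
    "read_growth_curves",
    "load_config",
    "save_config",
]


@dataclass
class RunConfig:
    """Parameters of a reproducible pipeline run; every field has a default
    except the input paths supplied on the command line."""

    beta: float = 0.40
    baseline_window: tuple | None = None
    t_eval: float | str = 50.0
    slope_window: int = 3
    k: int = 3
    cluster_seed: int = 0
    n_restarts: int = 25
    smoothing_window: int = 15
    regression_minutes: float = 90.0
    blank: float | None = None
    saturation_value: float = float(2**24 - 1)
    acceptor_gate: float = 2500.0
    flow_correction: str = "ratio"
    flow_reference: str = "glucose"
    condition_map: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell fluorescence trace table.

    Requires columns ``cell_id, frame, time_min, donor, acceptor``
    (optional: ``direct_acceptor``, ``background_donor``,
    ``background_acceptor``).  Time must be strictly increasing within
    each cell; violations are reported with row numbers.
    """
    table = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trace table {path} is missing columns: {missing}")
    bad_rows = []
    for cell, g in table.groupby("cell_id", sort=False):
        t = g["time_min"].to_numpy()
        nonmono = np.where(np.diff(t) <= 0)[0]
        bad_rows.extend(g.index[i + 1] for i in nonmono)
    if bad_rows:
        raise ValueError(
            f"time_min not strictly increasing within cells at rows {sorted(bad_rows)[:10]}"
        )
    return table


def write_trace_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_flow_table(path: str | Path) -> pd.DataFrame:
    """Read a flow event table (requires strain and condition columns)."""
    table = pd.read_csv(path)
    required = ["strain", "condition"] + FLOW_COLUMNS
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"flow table {path} is missing columns: {missing}")
    return table


def read_growth_curves(path: str | Path, blank: float | None = None) -> list[GrowthCurve]:
    """Read per-well OD curves from a (time_h, od[, well]) table."""
    table = pd.read_csv(path)
    missing = [c for c in ("time_h", "od") if c not in table.columns]
    if missing:
        raise ValueError(f"growth table {path} is missing columns: {missing}")
    if "well" not in table.columns:
        table = table.assign(well="A1")
    return [
        GrowthCurve(g["time_h"].to_numpy(), g["od"].to_numpy(), blank=blank, well=str(well))
        for well, g in table.groupby("well", sort=True)
    ]
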