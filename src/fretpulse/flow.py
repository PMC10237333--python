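"""Population FRET quantification from flow-cytometry event tables.

Gate chain, in order: remove events with saturating forward/side scatter,
subtract the empty-plasmid strain's median from every fluorescence channel,
estimate donor-into-FRET-channel bleedthrough from the donor-only (eCFP)
strain, keep events with direct acceptor fluorescence of at least 2500 a.u.
(inclusive), then compute per-event bleedthrough-corrected FRET ratios and
take per-condition medians.  The non-responsive sensor strain corrects for
kinase-independent signal: the corrected level is the condition-matched
ratio of sensor to NR medians (a subtraction variant is available), then
normalized to a reference condition.

The acceptor gate uses the direct-excitation acceptor channel: sensor
expression, not FRET state, should decide which events are bright enough
to quantify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLUOR_CHANNELS = ["donor_ch", "fret_ch", "direct_acceptor_ch"]
DEFAULT_ACCEPTOR_GATE = 2500.0

__all__ = [
    "FlowFretResult",
    "filter_saturating",
    "subtract_control_median",
    "estimate_bleedthrough_flow",
    "gate_min_acceptor",
    "condition_ratios",
    "nr_correct_and_normalize",
    "analyze_flow_experiment",
]


@dataclass
class FlowFretResult:
    """Per-condition medians, NR-corrected and reference-normalized levels."""

    table: pd.DataFrame  # condition, sensor_median, nr_median, corrected, normalized
    beta: float
    reference: str
    gate_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    correction: str = "ratio"


def filter_saturating(events: pd.DataFrame, saturation_value: float) -> pd.DataFrame:
    """Drop events whose forward or side scatter is at/above saturation."""
    if saturation_value <= 0:
        raise ValueError("saturation value must be positive")
    keep = (events["fsc"] < saturation_value) & (events["ssc"] < saturation_value)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d saturating-scatter events", n_removed)
    return events.loc[keep].reset_index(drop=True)


def subtract_control_median(events: pd.DataFrame, empty_events: pd.DataFrame) -> pd.DataFrame:
    """Subtract the empty-plasmid per-channel medians from every event."""
    if empty_events.empty:
        raise ValueError("empty-plasmid control table has no events")
    out = events.copy()
    for ch in FLUOR_CHANNELS:
        out[ch] = out[ch] - float(empty_events[ch].median())
    return out


def estimate_bleedthrough_flow(donor_only_events: pd.DataFrame, min_events: int = 100) -> float:
    """Bleedthrough fraction from the donor-only strain (after control subtraction).

    beta = median over events of FRET channel / donor channel, using
    events with positive donor signal.
    """
    pos = donor_only_events.loc[donor_only_events["donor_ch"] > 0]
    if len(pos) < min_events:
        raise ValueError(
            f"need >= {min_events} donor-only events with positive donor signal, got {len(pos)}"
        )
    return float((pos["fret_ch"] / pos["donor_ch"]).median())


def gate_min_acceptor(events: pd.DataFrame, threshold: float = DEFAULT_ACCEPTOR_GATE) -> pd.DataFrame:
    """Keep events with direct acceptor fluorescence >= threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("acceptor gate threshold must be >= 0")
    return events.loc[events["direct_acceptor_ch"] >= threshold].reset_index(drop=True)


def condition_ratios(events: pd.DataFrame, beta: float) -> pd.Series:
    """Per-condition median bleedthrough-corrected FRET ratio.

    ratio = (fret_ch - beta * donor_ch) / donor_ch per event; events with
    non-positive donor are dropped.  Raises if any condition loses all
    its events.
    """
    pos = events.loc[events["donor_ch"] > 0].copy()
    lost = set(events["condition"]) - set(pos["condition"])
    if lost:
        raise ValueError(f"conditions with no usable events: {sorted(lost)}")
    pos["fret_ratio"] = (pos["fret_ch"] - beta * pos["donor_ch"]) / pos["donor_ch"]
    return pos.groupby("condition")["fret_ratio"].median()


def nr_correct_and_normalize(
    sensor_medians: pd.Series,
    nr_medians: pd.Series,
    reference: str,
    correction: str = "ratio",
) -> pd.DataFrame:
    """Correct sensor medians by the non-responsive sensor, then normalize.

    ``correction="ratio"`` (default) divides condition-matched medians;
    ``"difference"`` subtracts them.  The corrected level is then divided
    by its value at the reference condition, which therefore maps to 1.
    """
    missing = set(sensor_medians.index) - set(nr_medians.index)
    if missing:
        raise ValueError(f"NR strain not measured for conditions: {sorted(missing)}")
    if reference not in sensor_medians.index:
        raise ValueError(f"reference condition {reference!r} not measured")
    nr = nr_medians.loc[sensor_medians.index]
    if correction == "ratio":
        corrected = sensor_medians / nr
    elif correction == "difference":
        corrected = sensor_medians - nr
    else:
        raise ValueError("correction must be 'ratio' or 'difference'")
    normalized = corrected / corrected.loc[reference]
    return pd.DataFrame(
        {
            "sensor_median": sensor_medians,
            "nr_median": nr,
            "corrected": corrected,
            "normalized": normalized,
        }
    ).rename_axis("condition").reset_index()


def analyze_flow_experiment(
    tables: dict[str, pd.DataFrame],
    saturation_value: float,
    acceptor_gate: float = DEFAULT_ACCEPTOR_GATE,
    reference: str = "glucose",
    correction: str = "ratio",
) -> FlowFretResult:
    """Run the full gate chain on a {strain: event table} experiment.

    Requires strains ``sensor``, ``sensor_NR``, ``empty``, ``donor_only``.
    Returns per-condition sensor and NR medians, NR-corrected levels
    normalized to the reference condition, and a gate-count audit table.
    """
    for strain in ("sensor", "sensor_NR", "empty", "donor_only"):
        if strain not in tables or tables[strain].empty:
            raise ValueError(f"missing control or sample strain: {strain!r}")

    unsat = {s: filter_saturating(t, saturation_value) for s, t in tables.items()}
    if any(t.empty for t in unsat.values()):
        raise ValueError("all events of a strain removed by the scatter filter")
    empty = unsat["empty"]
    corrected = {
        s: subtract_control_median(t, empty) for s, t in unsat.items() if s != "empty"
    }
    beta = estimate_bleedthrough_flow(corrected["donor_only"])
    gated = {
        s: gate_min_acceptor(corrected[s], acceptor_gate) for s in ("sensor", "sensor_NR")
    }
    counts = pd.DataFrame(
        {
            "total": {s: len(tables[s]) for s in ("sensor", "sensor_NR")},
            "after_scatter_filter": {s: len(unsat[s]) for s in ("sensor", "sensor_NR")},
            "after_acceptor_gate": {s: len(gated[s]) for s in ("sensor", "sensor_NR")},
        }
    ).rename_axis("strain")
    sensor_med = condition_ratios(gated["sensor"], beta)
    nr_med = condition_ratios(gated["sensor_NR"], beta)
    table = nr_correct_and_normalize(sensor_med, nr_med, reference, correction)
    return FlowFretResult(
        table=table,
        beta=beta,
        reference=reference,
        gate_counts=counts.reset_index(),
        correction=correction,
    )
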