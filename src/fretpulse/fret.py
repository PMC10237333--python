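"""Per-cell ratiometric FRET quantification and trace features.

Pipeline order is fixed: background subtraction, then donor-into-acceptor
bleedthrough correction, then the ratio (corrected acceptor / donor), then
baseline normalization (divide by the mean pre-perturbation ratio, so 1 is
the resting state).  Time is in minutes with t = 0 at the perturbation;
baseline frames are those with negative time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

DEFAULT_BLEEDTHROUGH = 0.40  # donor fraction spilling into the acceptor channel

__all__ = [
    "TraceQC",
    "subtract_background",
    "correct_bleedthrough",
    "compute_ratio",
    "normalize_baseline",
    "final_fret",
    "delta_normalized_fret",
    "max_slope",
    "expression_proxy",
    "phluorin_ratio",
    "quantify_traces",
    "extract_features",
    "analyze_traces",
]


@dataclass
class TraceQC:
    """Counts of frames and cells affected by quality rules."""

    n_negative_after_background: int = 0
    n_frames_dropped: int = 0
    cells_dropped: list = field(default_factory=list)


def subtract_background(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract per-frame background columns from both channels.

    Tables without ``background_donor`` / ``background_acceptor`` columns
    pass through unchanged (with a logged notice).  Negative corrected
    values are permitted and counted in the log.
    """
    if "background_donor" not in table.columns or "background_acceptor" not in table.columns:
        logger.info("no background columns present; skipping background subtraction")
        return table
    out = table.copy()
    out["donor"] = out["donor"] - out["background_donor"]
    out["acceptor"] = out["acceptor"] - out["background_acceptor"]
    n_neg = int((out["donor"] < 0).sum() + (out["acceptor"] < 0).sum())
    if n_neg:
        logger.warning("%d channel values negative after background subtraction", n_neg)
    return out.drop(columns=["background_donor", "background_acceptor"])


def correct_bleedthrough(donor, acceptor, beta: float = DEFAULT_BLEEDTHROUGH):
    """Corrected acceptor emission: acceptor minus ``beta`` times donor."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("bleedthrough fraction beta must be in [0, 1)")
    return np.asarray(acceptor, dtype=float) - beta * np.asarray(donor, dtype=float)


def compute_ratio(table: pd.DataFrame) -> tuple[pd.DataFrame, TraceQC]:
    """Per-frame FRET ratio (corrected acceptor / donor) per cell.

    Frames with non-positive donor are dropped and counted; cells losing
    all frames are listed in the QC record and excluded.
    Requires an ``acceptor_corr`` column (see :func:`correct_bleedthrough`).
    """
    if "acceptor_corr" not in table.columns:
        raise ValueError("table lacks 'acceptor_corr'; run correct_bleedthrough first")
    qc = TraceQC()
    ok = table["donor"] > 0
    qc.n_frames_dropped = int((~ok).sum())
    kept = table.loc[ok].copy()
    kept["ratio"] = kept["acceptor_corr"] / kept["donor"]
    qc.cells_dropped = sorted(set(table["cell_id"]) - set(kept["cell_id"]))
    if qc.cells_dropped:
        logger.warning("%d cells dropped (no frames with positive donor)", len(qc.cells_dropped))
    cols = [c for c in ("cell_id", "frame", "time_min") if c in kept.columns]
    return kept[cols + ["ratio"]].reset_index(drop=True), qc


def _baseline_mask(time_min: pd.Series, window: tuple[float, float] | None) -> pd.Series:
    if window is None:
        return time_min < 0
    lo, hi = window
    return (time_min >= lo) & (time_min <= hi)


def normalize_baseline(
    ratio_table: pd.DataFrame, baseline_window: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Divide each cell's ratio trace by its mean baseline ratio.

    The default baseline window is all frames with negative time.  Adds
    ``normalized_ratio`` and the per-cell ``baseline_mean`` (the basal,
    non-normalized FRET level).  Cells with an empty baseline raise.
    """
    mask = _baseline_mask(ratio_table["time_min"], baseline_window)
    base = ratio_table.loc[mask].groupby("cell_id")["ratio"].mean()
    missing = sorted(set(ratio_table["cell_id"]) - set(base.index))
    if missing:
        raise ValueError(f"cells with no baseline frames: {missing[:5]}")
    out = ratio_table.copy()
    out["baseline_mean"] = out["cell_id"].map(base)
    out["normalized_ratio"] = out["ratio"] / out["baseline_mean"]
    return out


def final_fret(normalized: np.ndarray) -> float:
    """Mean of the last 3 normalized FRET values of a trace."""
    v = np.asarray(normalized, dtype=float)
    if v.size < 3:
        raise ValueError("final FRET needs at least 3 frames")
    return float(v[-3:].mean())


def delta_normalized_fret(times, normalized, t_eval: float | str = 50.0) -> float:
    """Normalized FRET at the frame nearest ``t_eval`` minus 1.

    ``t_eval="end"`` evaluates at the last frame; a numeric ``t_eval``
    beyond the trace is clipped to the last frame with a logged notice.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(normalized, dtype=float)
    if isinstance(t_eval, str):
        if t_eval != "end":
            raise ValueError("t_eval must be a time in minutes or 'end'")
        return float(v[-1] - 1.0)
    if t_eval > t[-1]:
        logger.info("t_eval %.1f beyond trace end %.1f; clipping", t_eval, t[-1])
        t_eval = t[-1]
    idx = int(np.argmin(np.abs(t - t_eval)))
    return float(v[idx] - 1.0)


def max_slope(times, values, window: int = 3) -> float:
    """Maximum least-squares slope over contiguous frame windows (per minute).

    Evaluated on post-perturbation frames (time >= 0) when any exist,
    otherwise on the whole trace.  Exact on linear traces for any window.
    """
    if window < 2:
        raise ValueError("slope window must span at least 2 frames")
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    post = t >= 0
    if post.any():
        t, y = t[post], y[post]
    if t.size < window:
        raise ValueError("fewer frames than the slope window")
    tw = sliding_window_view(t, window)
    yw = sliding_window_view(y, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    return float(slopes.max())


def expression_proxy(donor, acceptor_corr) -> float:
    """Mean total sensor emission (donor + corrected acceptor) over frames."""
    return float(
        (np.asarray(donor, dtype=float) + np.asarray(acceptor_corr, dtype=float)).mean()
    )


def phluorin_ratio(f_405band, f_488band):
    """pH reporter ratio: emission under 380-420 nm over 460-500 nm excitation."""
    denom = np.asarray(f_488band, dtype=float)
    if np.any(denom == 0):
        raise ZeroDivisionError("pHluorin denominator channel contains zeros")
    result = np.asarray(f_405band, dtype=float) / denom
    return float(result) if result.ndim == 0 else result


def quantify_traces(
    table: pd.DataFrame,
    beta: float = DEFAULT_BLEEDTHROUGH,
    baseline_window: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TraceQC]:
    """Run background -> bleedthrough -> ratio -> baseline normalization.

    Returns the normalized long table (cell_id, time_min, ratio,
    baseline_mean, normalized_ratio), the background- and
    bleedthrough-corrected channel table, and the QC record.
    """
    df = subtract_background(table)
    df = df.sort_values(["cell_id", "time_min"], kind="stable").reset_index(drop=True)
    df = df.copy()
    df["acceptor_corr"] = correct_bleedthrough(df["donor"], df["acceptor"], beta)
    ratios, qc = compute_ratio(df)
    norm = normalize_baseline(ratios, baseline_window)
    return norm, df, qc


def extract_features(
    norm: pd.DataFrame,
    corrected: pd.DataFrame,
    t_eval: float | str = 50.0,
    slope_window: int = 3,
    baseline_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-cell trace features.

    One row per cell: ``basal_fret`` (mean raw ratio over the baseline),
    ``delta_norm_fret`` (normalized FRET at ``t_eval`` minus 1),
    ``max_slope`` (windowed regression, per minute), ``expression_proxy``
    (mean baseline donor + corrected acceptor), and ``final_fret``
    (mean of the last 3 normalized frames).
    """
    rows = []
    for cell, g in norm.groupby("cell_id", sort=True):
        t = g["time_min"].to_numpy()
        v = g["normalized_ratio"].to_numpy()
        rows.append(
            {
                "cell_id": cell,
                "basal_fret": float(g["baseline_mean"].iloc[0]),
                "delta_norm_fret": delta_normalized_fret(t, v, t_eval),
                "max_slope": max_slope(t, v, slope_window),
                "final_fret": final_fret(v),
            }
        )
    feats = pd.DataFrame(rows)
    base = corrected.loc[_baseline_mask(corrected["time_min"], baseline_window)]
    proxy = (
        (base["donor"] + base["acceptor_corr"])
        .groupby(base["cell_id"])
        .mean()
        .rename("expression_proxy")
    )
    feats = feats.merge(proxy, left_on="cell_id", right_index=True, how="left")
    return feats[
        ["cell_id", "basal_fret", "delta_norm_fret", "max_slope", "expression_proxy", "final_fret"]
    ]


def analyze_traces(
    table: pd.DataFrame,
    beta: float = DEFAULT_BLEEDTHROUGH,
    t_eval: float | str = 50.0,
    slope_window: int = 3,
    baseline_window: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TraceQC]:
    """Full microscopy-side pipeline: normalized traces plus per-cell features."""
    norm, corrected, qc = quantify_traces(table, beta, baseline_window)
    feats = extract_features(norm, corrected, t_eval, slope_window, baseline_window)
    return norm, feats, qc
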