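"""Shared fixtures: small hand-built tables with known arithmetic."""

import numpy as np
import pandas as pd
import pytest

from fretpulse import simulate


def make_trace_table(cells: dict) -> pd.DataFrame:
    """Long trace table from {cell_id: (times, donor, acceptor)}."""
    rows = []
    for cell, (t, d, a) in cells.items():
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell,
                    "frame": np.arange(len(t)),
                    "time_min": np.asarray(t, dtype=float),
                    "donor": np.asarray(d, dtype=float),
                    "acceptor": np.asarray(a, dtype=float),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@pytest.fixture
def tiny_table():
    # One cell, 5 frames, beta=0.4 arithmetic chosen by hand:
    # corrected acceptor = acceptor - 0.4*donor; ratio = corrected/donor.
    t = [-2.0, -1.0, 0.0, 1.0, 2.0]
    donor = [100.0, 100.0, 100.0, 100.0, 100.0]
    acceptor = [140.0, 140.0, 150.0, 160.0, 170.0]  # ratios 1.0,1.0,1.1,1.2,1.3
    return make_trace_table({"c1": (t, donor, acceptor)})


@pytest.fixture
def noise_free_design():
    p = simulate.ResponseClassParams(
        label="resp",
        basal_ratio=0.9,
        amplitude=0.3,
        rise_rate=0.2,
        delay=2.0,
        dip_depth=0.05,
        dip_rate=0.3,
    )
    return simulate.TraceSimulationDesign(
        classes=[(p, 1.0)],
        n_cells=8,
        additive_noise_sd=0.0,
        multiplicative_noise_cv=0.0,
        background_level=0.0,
        expression_cv=0.0,
        seed=11,
    )
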