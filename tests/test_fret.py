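"""fret_core: hand-checkable arithmetic, oracles, and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretpulse import fret, simulate
from tests.conftest import make_trace_table


class TestBleedthrough:
    def test_trivial_arithmetic(self):
        assert fret.correct_bleedthrough(100.0, 140.0, 0.4) == pytest.approx(100.0)

    def test_zero_donor(self):
        assert fret.correct_bleedthrough(0.0, 50.0, 0.4) == pytest.approx(50.0)

    def test_beta_range_validated(self):
        with pytest.raises(ValueError):
            fret.correct_bleedthrough(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            fret.correct_bleedthrough(1.0, 1.0, -0.1)

    def test_inversion_exact_on_noise_free_simulation(self, noise_free_design):
        """Forward bleedthrough then correction recovers the true ratio exactly."""
        table, truth = simulate.simulate_trace_set(noise_free_design)
        norm, corrected, _ = fret.quantify_traces(table, beta=0.40)
        g = truth.trajectories["resp"]
        for cell_id, cell in truth.cells.set_index("cell_id").iterrows():
            got = norm.loc[norm["cell_id"] == cell_id]
            t = got["time_min"].to_numpy()
            shape = g(t, amplitude=1.0) - g(t, amplitude=0.0)
            expected = cell["r0"] * (g(t, amplitude=0.0) + cell["amplitude"] * shape)
            np.testing.assert_allclose(got["ratio"].to_numpy(), expected, rtol=1e-12)

    @given(
        beta=st.floats(0.0, 0.95),
        donor=st.floats(1.0, 1e6),
        ratio=st.floats(0.01, 10.0),
    )
    def test_inversion_property(self, beta, donor, ratio):
        acceptor = donor * ratio + beta * donor
        corr = fret.correct_bleedthrough(donor, acceptor, beta)
        assert corr / donor == pytest.approx(ratio, rel=1e-9)


class TestRatioAndNormalization:
    def test_ratio_trivial(self, tiny_table):
        df = tiny_table.copy()
        df["acceptor_corr"] = fret.correct_bleedthrough(df["donor"], df["acceptor"], 0.4)
        ratios, qc = fret.compute_ratio(df)
        np.testing.assert_allclose(ratios["ratio"], [1.0, 1.0, 1.1, 1.2, 1.3])
        assert qc.n_frames_dropped == 0

    def test_requires_correction_first(self, tiny_table):
        with pytest.raises(ValueError, match="acceptor_corr"):
            fret.compute_ratio(tiny_table)

    def test_nonpositive_donor_frames_dropped_and_counted(self, tiny_table):
        df = tiny_table.copy()
        df.loc[2, "donor"] = 0.0
        df["acceptor_corr"] = df["acceptor"]
        ratios, qc = fret.compute_ratio(df)
        assert qc.n_frames_dropped == 1
        assert len(ratios) == 4

    def test_cell_with_no_positive_donor_listed(self, tiny_table):
        df = tiny_table.copy()
        df["donor"] = -1.0
        df["acceptor_corr"] = df["acceptor"]
        ratios, qc = fret.compute_ratio(df)
        assert qc.cells_dropped == ["c1"]
        assert ratios.empty

    def test_baseline_normalization_hand_value(self):
        # baseline ratios 1.0 and 1.2 -> mean 1.1; post ratio 1.65 -> 1.5
        tab = pd.DataFrame(
            {
                "cell_id": ["c", "c", "c"],
                "time_min": [-2.0, -1.0, 5.0],
                "ratio": [1.0, 1.2, 1.65],
            }
        )
        out = fret.normalize_baseline(tab)
        assert out["baseline_mean"].iloc[0] == pytest.approx(1.1)
        assert out["normalized_ratio"].iloc[-1] == pytest.approx(1.5)

    def test_no_baseline_frames_raises(self):
        tab = pd.DataFrame({"cell_id": ["c"], "time_min": [5.0], "ratio": [1.0]})
        with pytest.raises(ValueError, match="baseline"):
            fret.normalize_baseline(tab)

    def test_normalization_idempotent(self, tiny_table):
        norm, _, _ = fret.quantify_traces(tiny_table, beta=0.4)
        again = fret.normalize_baseline(
            norm.drop(columns=["ratio", "baseline_mean", "normalized_ratio"]).assign(
                ratio=norm["normalized_ratio"]
            )
        )
        np.testing.assert_allclose(
            again["normalized_ratio"], norm["normalized_ratio"], rtol=1e-12
        )

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        """Scaling both channels leaves ratio and normalized trace unchanged."""
        t = [-2.0, -1.0, 0.0, 1.0]
        donor = [100.0, 110.0, 105.0, 95.0]
        acceptor = [150.0, 160.0, 170.0, 180.0]
        base = make_trace_table({"c": (t, donor, acceptor)})
        scaled = make_trace_table(
            {"c": (t, [d * scale for d in donor], [a * scale for a in acceptor])}
        )
        n1, _, _ = fret.quantify_traces(base, beta=0.4)
        n2, _, _ = fret.quantify_traces(scaled, beta=0.4)
        np.testing.assert_allclose(
            n2["normalized_ratio"], n1["normalized_ratio"], rtol=1e-9
        )

    def test_background_subtraction(self):
        tab = make_trace_table({"c": ([-1.0, 0.0], [110.0, 120.0], [160.0, 170.0])})
        tab["background_donor"] = 10.0
        tab["background_acceptor"] = 20.0
        out = fret.subtract_background(tab)
        np.testing.assert_allclose(out["donor"], [100.0, 110.0])
        np.testing.assert_allclose(out["acceptor"], [140.0, 150.0])
        assert "background_donor" not in out.columns


class TestFeatures:
    def test_final_fret_mean_of_last_three(self):
        assert fret.final_fret([0.9, 1.2, 1.3, 1.4]) == pytest.approx(1.3)

    def test_final_fret_needs_three_frames(self):
        with pytest.raises(ValueError):
            fret.final_fret([1.0, 1.1])

    def test_delta_at_time_and_end(self):
        t = [0.0, 10.0, 50.0]
        v = [1.0, 1.1, 1.25]
        assert fret.delta_normalized_fret(t, v, 50.0) == pytest.approx(0.25)
        assert fret.delta_normalized_fret(t, v, "end") == pytest.approx(0.25)
        assert fret.delta_normalized_fret(t, v, 9.0) == pytest.approx(0.1)

    def test_delta_clips_beyond_trace(self):
        assert fret.delta_normalized_fret([0.0, 1.0], [1.0, 1.2], 99.0) == pytest.approx(0.2)

    def test_delta_rejects_bad_keyword(self):
        with pytest.raises(ValueError):
            fret.delta_normalized_fret([0.0, 1.0], [1.0, 1.2], "final")

    def test_max_slope_linear_exact(self):
        t = np.arange(10.0)
        assert fret.max_slope(t, 0.07 * t + 1.0) == pytest.approx(0.07, abs=1e-12)

    def test_max_slope_uses_post_perturbation_frames(self):
        # steep slope before t=0 must be ignored
        t = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        v = np.array([0.0, 5.0, 1.0, 1.1, 1.2])
        assert fret.max_slope(t, v) == pytest.approx(0.1)

    def test_max_slope_window_validation(self):
        with pytest.raises(ValueError):
            fret.max_slope([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], window=1)
        with pytest.raises(ValueError):
            fret.max_slope([0.0, 1.0], [1.0, 1.0], window=3)

    @given(st.integers(0, 2**32 - 1), st.integers(2, 6))
    @settings(max_examples=30, deadline=None)
    def test_max_slope_brute_force_oracle(self, seed, window):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(window, 40))
        t = np.sort(rng.uniform(0.0, 60.0, n))
        t += np.arange(n) * 1e-6  # enforce strict increase
        y = rng.normal(1.0, 0.3, n)
        expected = max(
            np.polyfit(t[i : i + window], y[i : i + window], 1)[0]
            for i in range(n - window + 1)
        )
        assert fret.max_slope(t, y, window) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_expression_proxy(self):
        assert fret.expression_proxy([100.0, 120.0], [120.0, 110.0]) == pytest.approx(225.0)

    def test_phluorin_ratio(self):
        assert fret.phluorin_ratio(50.0, 100.0) == pytest.approx(0.5)
        with pytest.raises(ZeroDivisionError):
            fret.phluorin_ratio(1.0, 0.0)

    def test_extract_features_tiny(self, tiny_table):
        norm, feats, qc = fret.analyze_traces(tiny_table, beta=0.4, t_eval="end")
        row = feats.iloc[0]
        assert row["basal_fret"] == pytest.approx(1.0)
        assert row["final_fret"] == pytest.approx(1.2)  # mean of 1.1,1.2,1.3
        assert row["delta_norm_fret"] == pytest.approx(0.3)
        assert row["max_slope"] == pytest.approx(0.1)
        # baseline donor 100 + corrected acceptor 100
        assert row["expression_proxy"] == pytest.approx(200.0)
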