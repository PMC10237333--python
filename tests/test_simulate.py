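"""synthetic_data: determinism, conservation laws, and trivial counts."""

import numpy as np
import pandas as pd
import pytest

from fretpulse import fret, simulate


class TestTraceSimulation:
    def test_deterministic_given_seed(self):
        d = simulate.null_design(n_cells=5, seed=42)
        t1, g1 = simulate.simulate_trace_set(d)
        t2, g2 = simulate.simulate_trace_set(d)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1.cells, g2.cells)

    def test_seed_changes_output(self):
        d = simulate.null_design(n_cells=5, seed=0)
        t1, _ = simulate.simulate_trace_set(d)
        t2, _ = simulate.simulate_trace_set(d, seed=1)
        assert not np.allclose(t1["donor"], t2["donor"])

    def test_channel_conservation_noise_free(self, noise_free_design):
        """donor + (acceptor - beta*donor) = expression, frame by frame."""
        table, truth = simulate.simulate_trace_set(noise_free_design)
        corr = table["acceptor"] - 0.40 * table["donor"]
        total = table["donor"] + corr
        expected = table["cell_id"].map(truth.cells.set_index("cell_id")["expression"])
        np.testing.assert_allclose(total, expected, rtol=1e-12)

    def test_null_design_flat_normalized_traces(self):
        d = simulate.null_design(
            n_cells=4,
            additive_noise_sd=0.0,
            multiplicative_noise_cv=0.0,
            background_level=0.0,
            expression_cv=0.0,
        )
        table, _ = simulate.simulate_trace_set(d)
        norm, _, _ = fret.quantify_traces(table, beta=0.40)
        np.testing.assert_allclose(norm["normalized_ratio"], 1.0, rtol=1e-12)

    def test_class_trajectory_plateau(self):
        p = simulate.ResponseClassParams(
            label="switch", amplitude=0.25, sustained_fraction=1.0, rise_rate=0.15
        )
        g = simulate.class_trajectory(p)
        assert g(np.array([1e6]))[0] == pytest.approx(1.25, abs=1e-9)

    def test_class_trajectory_transient_plateau(self):
        # f < 1: plateau is 1 + f*A even for large transient amplitude
        p = simulate.ResponseClassParams(
            label="weak", amplitude=0.70, sustained_fraction=0.08 / 0.70,
            rise_rate=1.0, decay_rate=0.2,
        )
        g = simulate.class_trajectory(p)
        assert g(np.array([1e6]))[0] == pytest.approx(1.08, abs=1e-9)

    def test_trajectory_is_one_before_perturbation(self):
        p = simulate.ResponseClassParams(label="x", amplitude=0.5, dip_depth=0.1)
        g = simulate.class_trajectory(p)
        np.testing.assert_allclose(g(np.array([-10.0, -1.0])), 1.0)

    def test_proportions_must_sum_to_one(self):
        p = simulate.ResponseClassParams(label="a")
        with pytest.raises(ValueError, match="sum to 1"):
            simulate.TraceSimulationDesign(classes=[(p, 0.6)])

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            simulate.ResponseClassParams(label="bad", basal_ratio=0.0)
        with pytest.raises(ValueError):
            simulate.ResponseClassParams(label="bad", sustained_fraction=1.5)
        with pytest.raises(ValueError):
            simulate.ResponseClassParams(label="bad", dip_depth=-0.1)

    def test_frame_grid(self):
        d = simulate.null_design(
            n_cells=1, frame_interval=2.0, baseline_duration=10.0, total_duration=60.0
        )
        assert d.times[0] == -10.0
        assert d.times.size == 30
        assert np.all(np.diff(d.times) == 2.0)

    def test_lognormal_moments(self):
        rng = np.random.default_rng(0)
        x = simulate._lognormal(rng, 2.0, 0.3, 200_000)
        assert x.mean() == pytest.approx(2.0, rel=0.01)
        assert x.std() / x.mean() == pytest.approx(0.3, rel=0.02)

    def test_lognormal_negative_mean_keeps_sign(self):
        rng = np.random.default_rng(0)
        x = simulate._lognormal(rng, -0.1, 0.5, 1000)
        assert (x < 0).all()
        assert x.mean() == pytest.approx(-0.1, rel=0.1)


class TestDoseSimulation:
    def test_zero_concentration_is_one(self):
        df = simulate.simulate_dose_response(0.24, 0.24, [0.0, 1.0, 2.0], noise_sd=0.0)
        assert (df.loc[df["concentration"] == 0.0, "final_norm_fret"] == 1.0).all()

    def test_half_saturation(self):
        df = simulate.simulate_dose_response(0.24, 0.24, [0.24, 1.0, 2.0], noise_sd=0.0)
        vals = df.loc[df["concentration"] == 0.24, "final_norm_fret"]
        np.testing.assert_allclose(vals, 1.12)

    def test_saturating_limit(self):
        df = simulate.simulate_dose_response(
            0.24, 0.24, [0.0, 1.0, 0.24e4], noise_sd=0.0
        )
        vals = df.loc[df["concentration"] == 0.24e4, "final_norm_fret"]
        np.testing.assert_allclose(vals, 1.24, atol=1e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate.simulate_dose_response(0.0, 0.24, [1.0])
        with pytest.raises(ValueError):
            simulate.simulate_dose_response(0.24, 0.24, [-1.0])


class TestGrowthSimulation:
    def test_sample_count(self):
        c = simulate.simulate_growth_curve(0.3, duration=0.5, interval=5.0, seed=0)
        assert c.od.size == 7

    def test_noise_free_exponential_limit(self):
        c = simulate.simulate_growth_curve(
            0.36, od0=0.01, carrying_capacity=1e9, lag=0.0, noise_sd=0.0, blank=0.05
        )
        y = np.log(c.od - 0.05)
        slopes = np.diff(y) / np.diff(c.time_h)
        np.testing.assert_allclose(slopes, 0.36, atol=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate.simulate_growth_curve(-0.1)
        with pytest.raises(ValueError):
            simulate.simulate_growth_curve(0.3, duration=0.0)
        with pytest.raises(ValueError):
            simulate.simulate_growth_curve(0.3, od0=2.0, carrying_capacity=1.0)


class TestFlowSimulation:
    def test_strain_tables_present(self):
        tables = simulate.simulate_flow_experiment(simulate.default_flow_design(), seed=0)
        assert set(tables) == {"sensor", "sensor_NR", "empty", "donor_only"}
        for tab in tables.values():
            assert {"fsc", "ssc", "donor_ch", "fret_ch", "direct_acceptor_ch"} <= set(
                tab.columns
            )

    def test_condition_coverage_must_match(self):
        with pytest.raises(ValueError, match="same conditions"):
            simulate.FlowDesign(sensor_ratio={"a": 1.0}, nr_ratio={"b": 0.5})
        with pytest.raises(ValueError):
            simulate.FlowDesign(sensor_ratio={}, nr_ratio={})

    def test_donor_only_noise_free_ratio_is_beta(self):
        d = simulate.FlowDesign(
            sensor_ratio={"a": 1.0},
            nr_ratio={"a": 0.5},
            noise_cv=0.0,
            background_median=0.0,
            saturating_fraction=0.0,
            n_events=500,
            seed=1,
        )
        t = simulate.simulate_flow_experiment(d)["donor_only"]
        np.testing.assert_allclose(t["fret_ch"] / t["donor_ch"], 0.40, rtol=1e-12)

    def test_saturating_fraction_binomial(self):
        d = simulate.default_flow_design(seed=7, n_events=20000)
        t = simulate.simulate_flow_experiment(d)["sensor"]
        frac = (t["fsc"] >= d.saturation_value).mean()
        # 3 binomial SEs around the design fraction
        se = np.sqrt(0.05 * 0.95 / len(t))
        assert abs(frac - 0.05) < 3 * se


class TestCalibration:
    def test_calibrated_slope_matches_target(self):
        design = simulate.mannose_design(calibrate=False)
        weak = design.classes[1][0]
        k = simulate.calibrate_rise_rate(weak, 0.26, design)
        measured = simulate._measured_mean_slope(
            simulate.ResponseClassParams(**{**weak.__dict__, "rise_rate": k}), design
        )
        assert measured == pytest.approx(0.26, abs=0.005)

    def test_unattainable_target_clamps_with_warning(self):
        design = simulate.mannose_design(calibrate=False)
        weak = design.classes[1][0]
        with pytest.warns(UserWarning, match="clamping"):
            k = simulate.calibrate_rise_rate(weak, 10.0, design, k_bounds=(0.05, 0.5))
        assert k == 0.5
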