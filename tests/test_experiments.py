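"""Figure-level experiment drivers: directional findings and determinism."""

import numpy as np
import pandas as pd
import pytest

from phosphorelay import build_relay, sweep_input
from phosphorelay.experiments import (
    bifunctional_km_scan,
    crosstalk_scan,
    dephos_rate_scan,
    length_scan,
    noise_analysis,
    robustness_sampling,
)
from phosphorelay.metrics import response_coefficient
from phosphorelay.steady import SteadyStateError


@pytest.fixture(scope="module")
def lengths24():
    return length_scan(lengths=(2, 4))


@pytest.fixture(scope="module")
def km_scan():
    return bifunctional_km_scan()


class TestLengthScan:
    def test_longer_relays_are_more_ultrasensitive(self):
        res = length_scan(lengths=(2, 3, 4, 5))
        best = res.table.groupby("length")["response_coefficient"].min()
        assert np.all(np.diff(best.to_numpy()) <= 0)

    def test_length4_peak_ultrasensitivity_is_intermediate(self, lengths24):
        t4 = lengths24.table.query("length == 4 and is_most_ultrasensitive")
        assert t4["layer"].item() in (2, 3)

    def test_length2_is_non_sigmoidal_everywhere(self, lengths24):
        t = lengths24.table
        rc2 = t.query("length == 2")["response_coefficient"]
        rc4_mid = t.query("length == 4 and layer == 2")["response_coefficient"].item()
        assert (rc2 > rc4_mid).all()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            length_scan(lengths=(1, 2))


class TestBifunctionalScan:
    def test_low_window_sensitivity_increases_with_km(self, km_scan):
        s = km_scan.table.sort_values("km")["sensitivity_low"].to_numpy()
        assert np.all(np.diff(s) > 0)  # off (km = inf) is largest

    def test_high_window_ordering_reverses_at_small_km(self, km_scan):
        t = km_scan.table.set_index("km_label")
        # an efficient bifunctional enzyme extends the responsive range:
        # in [2, 10] the Km = 0.1 relay outperforms both the plain relay
        # and the weakly binding enzyme
        assert t.loc["0.1", "sensitivity_high"] > t.loc["off", "sensitivity_high"]
        assert t.loc["0.1", "sensitivity_high"] > t.loc["100", "sensitivity_high"]

    def test_disabled_enzyme_equals_plain_sweep(self, km_scan, default_spec):
        grid = km_scan.curves["off"].inputs
        plain = sweep_input(default_spec, grid)
        np.testing.assert_allclose(
            km_scan.curves["off"].response, plain.response, atol=1e-9
        )


class TestCrosstalkScan:
    def test_activation_at_final_layer_lowers_saturation_input(self):
        res = crosstalk_scan(4, "activation", rates=[0.5])
        t = res.table.set_index("crosstalk_rate")
        assert t.loc[0.5, "input_90"] < t.loc[0.0, "input_90"]

    def test_inhibition_at_top_widens_range_preserving_max(self):
        res = crosstalk_scan(1, "inhibition", rates=[0.5])
        t = res.table.set_index("crosstalk_rate")
        assert t.loc[0.5, "input_90"] > t.loc[0.0, "input_90"]
        assert abs(t.loc[0.5, "max_response"] - t.loc[0.0, "max_response"]) < 0.02 * t.loc[
            0.0, "max_response"
        ]

    def test_zero_rate_row_is_the_default_sweep(self, default_spec):
        res = crosstalk_scan(3, "inhibition", rates=[0.1])
        grid = res.curves[0.0].inputs
        np.testing.assert_allclose(
            res.curves[0.0].response, sweep_input(default_spec, grid).response, atol=1e-9
        )

    def test_heatmap_is_tidy(self):
        res = crosstalk_scan(2, "activation", rates=[0.1, 0.5], n_points=50)
        assert set(res.heatmap.columns) == {"crosstalk_rate", "input", "response"}
        assert len(res.heatmap) == 3 * 50  # baseline + two rates

    @pytest.mark.parametrize("layer, mode", [(1, "activation"), (5, "inhibition"), (2, "x")])
    def test_invalid_points_rejected(self, layer, mode):
        with pytest.raises(ValueError):
            crosstalk_scan(layer, mode)


class TestRobustnessSampling:
    def test_ultrasensitivity_holds_across_parameter_space(self):
        df = robustness_sampling(150, seed=5)
        assert df["response_coefficient"].median() < 81.0
        assert "ok" in df and df["ok"].dtype == bool

    def test_default_parameters_reproduce_reference_coefficient(self, default_spec, default_grid):
        # a sample at the default parameter values must agree with the
        # sweep-based coefficient of the reference relay
        from phosphorelay.steady import analytic_curve

        rc_ref = response_coefficient(sweep_input(default_spec, default_grid), 2)
        curve = analytic_curve(default_spec)
        sub = curve.inputs <= 2.0
        rc_ana = response_coefficient(
            type(curve)(curve.inputs[sub], curve.response[sub]), 2
        )
        assert rc_ana == pytest.approx(rc_ref, rel=5e-3)

    def test_same_seed_same_table(self):
        a = robustness_sampling(40, seed=9)
        b = robustness_sampling(40, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_count_validated(self):
        with pytest.raises(ValueError):
            robustness_sampling(0, seed=1)


class TestDephosRateScan:
    def test_threshold_moves_with_dephosphorylation_rate(self):
        res = dephos_rate_scan((0.25, 0.5, 1.0, 2.0))
        thr = res.table["threshold_input"].to_numpy()
        assert np.all(np.diff(thr) > 0)

    def test_unit_rate_row_equals_default(self, default_spec, default_grid):
        res = dephos_rate_scan((1.0,))
        np.testing.assert_allclose(
            res.curves[1.0].response, sweep_input(default_spec, default_grid).response,
            atol=1e-9,
        )

    def test_zero_rate_rejected(self):
        with pytest.raises(SteadyStateError):
            dephos_rate_scan((0.0, 1.0))


class TestNoiseAnalysis:
    def test_small_scan_structure_and_determinism(self):
        kw = dict(
            lengths=(2, 4),
            levels=range(0, 201, 25),
            burn_in=10.0,
            sample_time=30.0,
            record_interval=0.1,
            seed=13,
        )
        a = noise_analysis(**kw)
        b = noise_analysis(**kw)
        pd.testing.assert_frame_equal(a.stats, b.stats)
        assert set(a.stats.columns) == {"length", "level", "layer", "mean", "std", "snr"}
        assert sorted(a.summary["length"]) == [2, 4]
        assert "median_final_snr_100_200" in a.summary
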