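"""Steady-state solves, continuation sweeps and the closed-form curve."""

import numpy as np
import pytest

from phosphorelay import (
    RelayState,
    SteadyStateError,
    analytic_curve,
    analytic_state,
    build_relay,
    max_flux,
    solve_steady,
    sweep_input,
)
from phosphorelay.steady import ResponseCurve, _phospho_from_flux

# Frozen independent oracle: fixed-step RK4 integration of the default
# four-layer system over 1e4 time units at step 1e-3, values to 6 decimals.
ORACLE_STEADY = {
    0.1: (0.100001, 0.100100, 0.109878, 0.990000),
    0.5: (0.501111, 0.522179, 0.904560, 4.749444),
    1.0: (1.243644, 2.959114, 7.040886, 8.756356),
}


class TestSolveSteady:
    def test_zero_input_is_fully_unphosphorylated(self, default_spec):
        st = solve_steady(default_spec, 0.0)
        np.testing.assert_allclose(st.phospho, 0.0, atol=1e-12)

    def test_totals_conserved_at_steady_state(self, default_spec):
        st = solve_steady(default_spec, 1.0)
        # L2p + L2 = 10 exactly: unphosphorylated is totals minus phosphorylated
        assert np.all(st.phospho >= 0) and np.all(st.phospho <= 10)

    @pytest.mark.parametrize("k1", sorted(ORACLE_STEADY))
    def test_matches_brute_force_integration_oracle(self, default_spec, k1):
        st = solve_steady(default_spec, k1)
        np.testing.assert_allclose(st.phospho, ORACLE_STEADY[k1], atol=5e-6)

    def test_phosphate_channel_regime(self, default_spec):
        """At low input the relay passes phosphate straight through: the
        intermediate layers stay below 5% of their totals while the final
        layer carries more phosphate than any of them."""
        st = solve_steady(default_spec, 0.1)
        intermediates = st.phospho[1:3]
        assert np.all(intermediates < 0.05 * 10)
        assert st.phospho[-1] > intermediates.max()

    def test_no_outflux_is_rejected(self):
        spec = build_relay(4, hydrolysis_rate=0.0)
        with pytest.raises(SteadyStateError, match="no steady state"):
            solve_steady(spec, 1.0)

    def test_negative_input_rejected(self, default_spec):
        with pytest.raises(ValueError):
            solve_steady(default_spec, -0.1)


class TestSweepInput:
    def test_final_layer_monotone_and_bounded(self, default_spec, default_grid):
        curve = sweep_input(default_spec, default_grid)
        r4 = curve.layer(4)
        assert np.all(np.diff(r4) >= -1e-9)
        assert np.all(r4 <= 10.0)

    def test_continuation_equals_independent_solves(self, default_spec):
        grid = np.linspace(0.0, 2.0, 21)
        curve = sweep_input(default_spec, grid)
        for j in [3, 10, 17, 20]:
            st = solve_steady(default_spec, grid[j], initial_guess=RelayState.zeros(default_spec))
            np.testing.assert_allclose(curve.response[j], st.phospho, atol=1e-7)

    def test_single_zero_input(self, default_spec):
        curve = sweep_input(default_spec, [0.0])
        np.testing.assert_allclose(curve.response, 0.0, atol=1e-12)

    @pytest.mark.parametrize("grid", [[], [1.0, 0.5], [-1.0, 0.0]])
    def test_bad_grids_rejected(self, default_spec, grid):
        with pytest.raises(ValueError):
            sweep_input(default_spec, grid)

    def test_failure_reports_offending_input(self):
        spec = build_relay(4, hydrolysis_rate=0.0)
        with pytest.raises(SteadyStateError, match="k1=1"):
            sweep_input(spec, [0.0, 1.0])


class TestAnalyticCurve:
    def test_zero_flux_is_origin(self, default_spec):
        curve = analytic_curve(default_spec, flux_grid=[0.0, 5.0])
        np.testing.assert_allclose(curve.response[0], 0.0)
        # at J = 5 the final layer holds J / k_hyd = 5 exactly
        assert curve.response[-1, -1] == pytest.approx(5.0)

    def test_max_flux_brackets_feasibility(self, default_spec):
        jmax = max_flux(default_spec)
        assert _phospho_from_flux(default_spec, 0.999999 * jmax) is not None
        assert _phospho_from_flux(default_spec, 1.000001 * jmax) is None

    def test_beyond_saturation_rejected(self, default_spec):
        jmax = max_flux(default_spec)
        with pytest.raises(SteadyStateError, match="saturat"):
            analytic_curve(default_spec, flux_grid=[0.0, 1.01 * jmax])

    def test_input_strictly_increasing_in_flux(self, default_spec):
        curve = analytic_curve(default_spec, n_points=300)
        assert np.all(np.diff(curve.inputs) > 0)

    def test_agrees_with_numerical_sweep(self, default_spec):
        """The parametric solution and the ODE continuation are the same
        curve to max abs difference < 1e-6 over the pre-saturation range."""
        grid = np.linspace(0.0, 2.0, 60)[1:]
        sw = sweep_input(default_spec, grid)
        ana = np.array([analytic_state(default_spec, k).phospho for k in grid])
        assert np.max(np.abs(sw.response - ana)) < 1e-6

    def test_requires_plain_relay(self):
        with pytest.raises(ValueError):
            analytic_curve(build_relay(4, deact_rates=(0, 0.5, 0, 0)))
        with pytest.raises(ValueError):
            analytic_curve(build_relay(4, bifunctional=True))

    def test_no_outflux_rejected(self):
        with pytest.raises(SteadyStateError):
            analytic_curve(build_relay(4, hydrolysis_rate=0.0))


class TestResponseCurveIO:
    def test_csv_round_trip_12_significant_digits(self, default_spec, tmp_path):
        curve = sweep_input(default_spec, np.linspace(0, 2, 20))
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "input,L1p,L2p,L3p,L4p"
        back = ResponseCurve.from_csv(path)
        np.testing.assert_allclose(back.response, curve.response, rtol=1e-11)
        np.testing.assert_allclose(back.inputs, curve.inputs, rtol=1e-11)

    def test_rejects_mismatched_rows(self):
        with pytest.raises(ValueError):
            ResponseCurve(np.array([0.0, 1.0]), np.zeros((3, 4)))

    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValueError):
            ResponseCurve(np.array([0.0, 1.0, 1.0]), np.zeros((3, 4)))
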