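"""Relay specification, ODE right-hand side and reaction-network compilation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosphorelay import RelayState, build_relay, compile_reactions, ode_rhs
from phosphorelay.model import _rhs_vector


class TestBuildRelay:
    def test_defaults_are_the_reference_parameterization(self):
        spec = build_relay(4)
        assert spec.totals == (10.0,) * 4
        assert spec.transfer_rates == (1.0,) * 3
        assert spec.hydrolysis_rate == 1.0
        assert spec.act_rates == (0.0,) * 4
        assert spec.deact_rates == (0.0,) * 4
        assert not spec.bifunctional

    @pytest.mark.parametrize(
        "n_layers, overrides",
        [
            (1, {}),                                     # too short
            (4, {"act_rates": (0.5, 0, 0, 0)}),          # layer-1 self-phosphorylation
            (4, {"transfer_rates": (1.0, -1.0, 1.0)}),   # negative rate
            (4, {"totals": (10, 0, 10, 10)}),            # nonpositive total
            (4, {"frobnicate": 1.0}),                    # unknown field
            (4, {"transfer_rates": (1.0, 1.0)}),         # wrong length
        ],
    )
    def test_invalid_specs_rejected(self, n_layers, overrides):
        with pytest.raises(ValueError):
            build_relay(n_layers, overrides)

    def test_overrides_applied_and_km(self):
        spec = build_relay(3, bifunctional=True, k_on=0.1, k_cat=1.0)
        assert spec.bifunctional and spec.km == pytest.approx(10.0)


class TestOdeRhs:
    def test_empty_system_is_quiescent(self, default_spec):
        d = ode_rhs(default_spec, RelayState.zeros(default_spec), 0.0)
        assert np.all(d.phospho == 0) and d.complex == 0

    def test_single_transfer_term(self, default_spec):
        # L1p = 10: only the k2 transfer (1.0 * 10 * 10) is active
        state = RelayState(np.array([10.0, 0, 0, 0]))
        d = ode_rhs(default_spec, state, 0.0)
        np.testing.assert_allclose(d.phospho, [-100.0, 100.0, 0.0, 0.0])

    def test_dimension_mismatch_rejected(self, default_spec):
        with pytest.raises(ValueError):
            ode_rhs(default_spec, RelayState(np.zeros(3)), 1.0)

    @given(
        n=st.integers(2, 5),
        data=st.data(),
        k1=st.floats(0, 5),
        bifunctional=st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_total_phosphate_bookkeeping(self, n, data, k1, bifunctional):
        """d(total phosphate)/dt equals influx minus outflux for any state.

        Total phosphate is sum(Lip) + C (the complex carries one phosphoryl
        group).  Transfers shuttle phosphate without creating or destroying
        it, so the only sources are the input and cross-activation, the only
        sinks hydrolysis, cross-inhibition and catalytic release.  Holds for
        any state and any parameterization.
        """
        rates = st.floats(0, 3)
        spec = build_relay(
            n,
            act_rates=(0.0,) + tuple(data.draw(rates) for _ in range(n - 1)),
            deact_rates=tuple(data.draw(rates) for _ in range(n)),
            bifunctional=bifunctional,
            k_on=data.draw(rates),
            k_cat=data.draw(rates),
        )
        c = data.draw(st.floats(0, 2)) if bifunctional else 0.0
        phospho = np.array([data.draw(st.floats(0, 8)) for _ in range(n)])
        state = RelayState(phospho, c)
        d = ode_rhs(spec, state, k1)
        free = np.array(spec.totals) - phospho
        if bifunctional:
            free[0] -= c
            free[-1] -= c
        influx = k1 * free[0] + float(np.dot(spec.act_rates, free))
        outflux = (
            spec.hydrolysis_rate * phospho[-1]
            + float(np.dot(spec.deact_rates, phospho))
            + (spec.k_cat * c if bifunctional else 0.0)
        )
        total_change = d.phospho.sum() + d.complex
        assert total_change == pytest.approx(influx - outflux, abs=1e-9, rel=1e-9)

    def test_conservation_against_finite_difference(self, default_spec):
        """Integrator-level check: Li + Lip stays constant along a trajectory."""
        from scipy.integrate import solve_ivp

        spec = build_relay(4, bifunctional=True, k_on=1.0, k_cat=1.0)
        y0 = np.array([1.0, 2.0, 3.0, 4.0, 0.5])
        sol = solve_ivp(
            lambda t, y: _rhs_vector(spec, y, 1.3), (0, 5), y0, rtol=1e-10, atol=1e-12
        )
        p = sol.y[:4]
        c = sol.y[4]
        # free + phospho + complex share per layer must be constant; since free
        # is defined as total - phospho (- complex), the bound quantity is
        # phospho (+ complex) staying within totals and the flux balance at the
        # end: total phosphate = integral of influx - outflux.
        assert np.all(p <= 10 + 1e-9) and np.all(p >= -1e-9) and np.all(c >= -1e-9)
        assert np.all(p[0] + c <= 10 + 1e-9) and np.all(p[3] + c <= 10 + 1e-9)

    def test_flux_balance_at_steady_state(self, default_spec):
        """Phosphate influx k1*L1 equals outflux k_hyd*LNp at steady state."""
        from phosphorelay import solve_steady

        st_ = solve_steady(default_spec, 0.7)
        influx = 0.7 * (10 - st_.phospho[0])
        outflux = default_spec.hydrolysis_rate * st_.phospho[-1]
        assert influx == pytest.approx(outflux, abs=1e-8)


class TestCompileReactions:
    def test_default_network_counts_and_constants(self, default_network):
        assert default_network.species["L1"] == 100
        assert all(default_network.species[f"L{i}p"] == 0 for i in range(1, 5))
        by_rate = sorted(r.rate for r in default_network.reactions)
        # activation 0.01, three transfers at 0.1, hydrolysis at 1.0
        assert by_rate == [0.01, 0.1, 0.1, 0.1, 1.0]

    def test_every_reaction_conserves_layer_totals(self, default_spec):
        spec = default_spec.with_(bifunctional=True)
        net = compile_reactions(spec, signal_mode="noisy-cascade")
        for rx in net.reactions:
            delta = {}
            for name, cnt in rx.reactants:
                delta[name] = delta.get(name, 0) - cnt
            for name, cnt in rx.products:
                delta[name] = delta.get(name, 0) + cnt
            for group in net.conserved_groups:
                assert sum(delta.get(name, 0) for name in group) == 0, rx.format()

    def test_reaction_orders_at_most_two(self, default_spec):
        net = compile_reactions(default_spec.with_(bifunctional=True))
        for rx in net.reactions:
            assert sum(c for _, c in rx.reactants) <= 2

    def test_export_text_round_readable(self, default_network):
        text = default_network.export_text()
        assert "L1 + S -> L1p + S @ 0.01" in text
        assert "L4p -> L4 @ 1" in text
        assert len(text.strip().splitlines()) == len(default_network.reactions)

    @pytest.mark.parametrize("bad", [0, -5, 2.5])
    def test_count_scale_validated(self, default_spec, bad):
        with pytest.raises(ValueError):
            compile_reactions(default_spec, count_scale=bad)

    def test_totals_scale_counts(self):
        spec = build_relay(2, totals=(5.0, 20.0))
        net = compile_reactions(spec, count_scale=100)
        assert net.species["L1"] == 50 and net.species["L2"] == 200
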