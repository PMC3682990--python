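import numpy as np
import pytest
from scipy.linalg import expm

from isletins import (
    ZERO_STATE,
    IsletState,
    equilibrium,
    new_to_peripheral_ratio,
    rhs,
    simulate_clamp,
    time_to_fraction,
    total_intra_islet_monomer,
)
from isletins.kinetics import SimulationTrace, with_rates


def linear_cascade_matrix(p):
    """System matrix of the model with aggregation switched off (q = q_hat = 0)."""
    return np.array(
        [
            [-p.p, 0.0, 0.0, 0.0],
            [3.0 * p.p, -p.p_hat, 0.0, 0.0],
            [0.0, 2.0 * p.p_hat, -(p.c + p.d_i), 0.0],
            [0.0, 0.0, p.k, -p.d_i],
        ]
    )


class TestRhs:
    @pytest.mark.parametrize("G", [0.0, 4.0, 7.0, 16.5])
    def test_vanishes_at_equilibrium(self, params, G):
        eq = equilibrium(params, G)
        np.testing.assert_allclose(rhs(eq, G, params), 0.0, atol=1e-10)

    def test_empty_islet_without_glucose_is_static(self, params):
        np.testing.assert_array_equal(rhs(ZERO_STATE, 0.0, params), 0.0)

    def test_secretion_enters_as_hexamer_sixth(self, params):
        """From the empty state all flux is hexamer influx at s(G)/6."""
        deriv = rhs(ZERO_STATE, 7.0, params)
        s7 = params.secretion_rate(7.0)
        assert deriv[0] == pytest.approx(s7 / 6.0)
        np.testing.assert_array_equal(deriv[1:], 0.0)

    def test_negative_states_unrepresentable(self):
        with pytest.raises(ValueError):
            IsletState(-1.0, 0.0, 0.0, 0.0)

    def test_negative_glucose_rejected(self, params):
        with pytest.raises(ValueError):
            rhs(ZERO_STATE, -1.0, params)


class TestEquilibrium:
    def test_zero_secretion_gives_empty_islet(self, params):
        eq = equilibrium(params, 0.0)
        np.testing.assert_array_equal(eq.to_array(), 0.0)

    def test_closed_form_structure_at_physiological_glucose(self, params):
        """At G = 7 the aggregation corrections are numerically negligible, so
        h* ~ s/(6p), d* ~ s/(2 p_hat), m* = s/(c+d_i), ip* = 3 m*."""
        s = params.secretion_rate(7.0)
        eq = equilibrium(params, 7.0)
        assert eq.m == pytest.approx(s / (params.c + params.d_i))
        assert eq.ip == pytest.approx(3.0 * eq.m, rel=1e-12)
        assert eq.d == pytest.approx(s / (2.0 * params.p_hat), rel=1e-4)
        assert eq.h == pytest.approx(s / (6.0 * params.p), rel=1e-6)
        # the aggregation corrections themselves
        assert params.q * eq.d**3 < 1e-10
        assert params.q_hat * eq.m**2 < 1e-3

    def test_components_nondecreasing_in_glucose(self, params):
        grid = np.linspace(0.0, 25.0, 26)
        states = np.array([equilibrium(params, G).to_array() for G in grid])
        assert np.all(np.diff(states, axis=0) >= -1e-12)

    def test_ratio_matches_equilibrium_components(self, params):
        ratio = new_to_peripheral_ratio(params)
        assert ratio == pytest.approx(params.d_i / params.k)
        for G in (2.0, 5.0, 20.0):
            eq = equilibrium(params, G)
            assert eq.m / eq.ip == pytest.approx(ratio, rel=1e-12)

    def test_total_monomer_closed_form(self, params):
        for G in (4.0, 7.0):
            s = params.secretion_rate(G)
            expected = (1.0 + params.k / params.d_i) * s / (params.c + params.d_i)
            assert total_intra_islet_monomer(params, G) == pytest.approx(expected)

    def test_flux_conservation_under_transient_rate_changes(self, params):
        """m* and ip* pass the whole secretion flux and are invariant to 10-fold
        changes in the dissolution/aggregation rates; h* and d* are not."""
        base = equilibrium(params, 7.0)
        scaled = with_rates(
            params, p=params.p * 10, p_hat=params.p_hat * 10,
            q=params.q * 10, q_hat=params.q_hat * 10,
        )
        eq = equilibrium(scaled, 7.0)
        assert eq.m == pytest.approx(base.m, rel=1e-12)
        assert eq.ip == pytest.approx(base.ip, rel=1e-12)
        assert eq.h != pytest.approx(base.h, rel=0.5)
        assert eq.d != pytest.approx(base.d, rel=0.5)


class TestSimulateClamp:
    def test_stationary_when_started_at_equilibrium(self, params):
        eq = equilibrium(params, 7.0)
        trace = simulate_clamp(params, 7.0, 50.0, init=eq)
        rel = np.abs(trace.y / eq.to_array() - 1.0)
        assert rel.max() < 1e-6

    def test_converges_to_closed_form_equilibrium(self, params):
        trace = simulate_clamp(params, 10.0, 600.0)
        eq = equilibrium(params, 10.0).to_array()
        np.testing.assert_allclose(trace.y[-1], eq, rtol=1e-3)

    def test_matches_analytic_linear_cascade(self, params):
        """With aggregation off the model is a linear cascade; the simulated
        trace must match the matrix-exponential solution to 1e-6 relative."""
        lin = with_rates(params, q=0.0, q_hat=0.0)
        G = 10.0
        A = linear_cascade_matrix(lin)
        b = np.array([lin.secretion_rate(G) / 6.0, 0.0, 0.0, 0.0])
        ystar = -np.linalg.solve(A, b)
        trace = simulate_clamp(lin, G, 60.0, dt_out=5.0)
        for t, y in zip(trace.t[1:], trace.y[1:]):
            exact = ystar + expm(A * t) @ (-ystar)
            np.testing.assert_allclose(y, exact, rtol=1e-6, atol=1e-8)

    def test_normalized_peripheral_profile_independent_of_glucose(self, params):
        """In the linear regime ip(t)/ip* is the same curve at every clamp level."""
        lin = with_rates(params, q=0.0, q_hat=0.0)
        profiles = []
        for G in (5.0, 10.0, 15.0):
            trace = simulate_clamp(lin, G, 60.0, dt_out=2.0)
            profiles.append(trace.component("ip") / equilibrium(lin, G).ip)
        np.testing.assert_allclose(profiles[0], profiles[1], rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(profiles[0], profiles[2], rtol=1e-8, atol=1e-10)

    def test_invalid_arguments(self, params):
        with pytest.raises(ValueError):
            simulate_clamp(params, 7.0, 0.0)
        with pytest.raises(ValueError):
            simulate_clamp(params, -1.0, 10.0)

    def test_trace_dataframe_layout(self, params):
        df = simulate_clamp(params, 7.0, 10.0, dt_out=1.0).to_dataframe()
        assert list(df.columns) == [
            "time_min", "h_pM", "d_pM", "m_pM", "Ip_pM",
            "total_monomer_pM", "glucose_mM",
        ]
        np.testing.assert_allclose(
            df["total_monomer_pM"], df["m_pM"] + df["Ip_pM"]
        )


class TestTimeToFraction:
    def test_constant_trace_is_immediate(self, params):
        eq = equilibrium(params, 7.0)
        n = 5
        trace = SimulationTrace(
            t=np.arange(n, dtype=float),
            y=np.tile(eq.to_array(), (n, 1)),
            glucose=7.0,
        )
        assert time_to_fraction(trace, "ip", 0.9, eq.ip) == 0.0

    def test_never_crossing_returns_sentinel(self, params):
        trace = simulate_clamp(params, 10.0, 5.0, dt_out=0.5)
        assert time_to_fraction(trace, "ip", 0.9, equilibrium(params, 10.0).ip) is None

    def test_matches_analytic_crossing_time(self, params):
        """The 90% rise time of ip after a 0 -> 10 mM step is ~25.5 min, in
        agreement with the matrix-exponential solution of the linear cascade."""
        trace = simulate_clamp(params, 10.0, 120.0, dt_out=0.1)
        eq = equilibrium(params, 10.0)
        t90 = time_to_fraction(trace, "ip", 0.9, eq.ip)
        assert t90 == pytest.approx(25.54, abs=0.1)
        t50 = time_to_fraction(trace, "ip", 0.5, eq.ip)
        assert t50 == pytest.approx(11.367, abs=0.05)

    def test_unknown_component_rejected(self, params):
        trace = simulate_clamp(params, 10.0, 5.0, dt_out=1.0)
        with pytest.raises(KeyError):
            time_to_fraction(trace, "bogus", 0.9, 1.0)
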