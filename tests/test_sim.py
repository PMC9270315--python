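"""Time-domain simulator: transport, junctions, equilibria, attractors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capnet.network import three_node_network
from capnet.sim import (
    Perturbation,
    envelope_growth_rate,
    junction_update,
    limit_cycle_metrics,
    oscillation_metrics,
    retarded_time,
    simulate,
)
from capnet.splitting import make_split_rule
from capnet.steady import find_starting_state, trivial_state


class TestRetardedTime:
    def test_unit_velocity_unit_transit(self):
        t = np.arange(0.0, 3.0, 0.01)
        assert retarded_time(t, np.ones_like(t)) == pytest.approx(1.0, abs=1e-9)

    def test_half_velocity_double_transit(self):
        t = np.arange(0.0, 5.0, 0.01)
        assert retarded_time(t, 0.5 * np.ones_like(t)) == pytest.approx(2.0, abs=1e-9)

    def test_linear_ramp_against_quadratic_solution(self):
        # U(s) = 1 + 0.5 s on [0, 1.2]: the transit integral gives
        # 0.25 s*^2 + s* - 0.56 = 0  ->  s* = -2 + sqrt(4 + 2.24)
        t = np.arange(0.0, 1.2 + 1e-12, 1e-4)
        tau = retarded_time(t, 1.0 + 0.5 * t)
        s_star = -2.0 + math.sqrt(4.0 + 2.24)
        assert tau == pytest.approx(1.2 - s_star, abs=1e-6)

    def test_initial_transient_sentinel(self):
        t = np.arange(0.0, 0.5, 0.01)
        assert retarded_time(t, np.ones_like(t)) is None


class TestJunctionUpdate:
    def test_converging_equal_haematocrits(self):
        (h,) = junction_update((1.0, 0.5), (0.3, 0.3), (1.5,))
        assert h == pytest.approx(0.3, rel=1e-12)

    def test_diverging_below_threshold_everything_to_sibling(self):
        rule = make_split_rule(20.0, 20.0, 20.0, 0.45)
        h_fav, h_other = junction_update((1.0,), (0.45,), (0.01, 0.99), rule)
        assert h_fav == 0.0
        assert h_other * 0.99 == pytest.approx(0.45, rel=1e-12)

    @given(
        qp=st.floats(0.1, 5.0),
        hp=st.floats(0.0, 0.9),
        frac=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_red_cell_flux_conserved_at_diverging_node(self, qp, hp, frac):
        rule = make_split_rule(20.0, 20.0, 20.0, 0.45)
        q_fav, q_other = qp * frac, qp * (1.0 - frac)
        h_fav, h_other = junction_update((qp,), (hp,), (q_fav, q_other), rule)
        flux_in = qp * hp
        flux_out = q_fav * h_fav + q_other * h_other
        assert flux_out == pytest.approx(flux_in, abs=1e-12 * max(1.0, flux_in))

    def test_conservation_error_on_dead_end(self):
        with pytest.raises(ValueError):
            junction_update((1.0, 1.0), (0.4, 0.4), (0.0,))


class TestEquilibria:
    def test_trivial_state_is_a_fixed_point(self):
        spec = three_node_network(0.5, 0.45)
        res = simulate(spec, 20.0, dt=0.01)
        assert np.max(np.abs(res.series("Q", 3))) < 1e-12
        assert np.max(np.abs(res.series("Hbar", 4) - 0.45)) < 1e-12
        assert np.max(np.abs(res.series("Q", 2) - 1.0)) < 1e-12

    def test_nontrivial_state_is_a_fixed_point(self):
        base = find_starting_state(0.5, "I", H0_start=0.5)
        spec = three_node_network(0.5, 0.5)
        res = simulate(spec, 10.0, dt=0.01, init=base)
        assert np.max(np.abs(res.series("Q", 3) + base.Q3)) < 1e-8
        assert np.max(np.abs(res.series("Hbar", 4) - base.H4)) < 1e-8

    def test_uniform_haematocrit_keeps_viscosity_constant(self):
        spec = three_node_network(1.0, 0.3)
        res = simulate(spec, 5.0, dt=0.01)
        assert np.max(np.abs(res.mubar - res.mubar[0])) < 1e-13

    def test_conservation_residuals_tracked(self):
        spec = three_node_network(0.5, 0.45)
        res = simulate(spec, 50.0, dt=0.01, perturbation=Perturbation(-1e-6))
        assert res.metadata["max_node_residual"] < 1e-12
        assert res.metadata["max_rbc_residual"] < 1e-12


class TestAttractors:
    """Perturbation-sign selection of the long-time attractor at (0.5, 0.45)."""

    def test_positive_perturbation_reaches_a_steady_state(self):
        spec = three_node_network(0.5, 0.45)
        res = simulate(spec, 400.0, dt=0.01,
                       perturbation=Perturbation(+1e-6), save_stride=5)
        q3 = res.series("Q", 3)
        # settles to top-to-bottom flow (Case II side)
        assert q3[-1] > 5e-3
        tail = q3[res.times > 350.0]
        assert (tail.max() - tail.min()) < 1e-4

    def test_negative_perturbation_excites_oscillations(self):
        spec = three_node_network(0.5, 0.45)
        res = simulate(spec, 500.0, dt=0.01,
                       perturbation=Perturbation(-1e-6), save_stride=5)
        q3 = res.series("Q", 3)
        tail = q3[res.times > 250.0]
        assert tail.max() < 0.0  # bottom-to-top flow throughout
        assert (tail.max() - tail.min()) > 0.01  # large sustained swing


class TestMetrics:
    def test_synthetic_sinusoid_amplitude_and_period(self):
        t = np.arange(0.0, 400.0, 0.05)
        y = 0.7 + 0.23 * np.sin(2 * np.pi * t / 17.0)
        m = oscillation_metrics(t, y, transient_fraction=0.3)
        assert m["oscillatory"]
        assert m["amplitude"] == pytest.approx(0.23, rel=0.01)
        assert m["period"] == pytest.approx(17.0, rel=0.01)
        assert m["converged"]

    def test_steady_series_has_zero_amplitude(self):
        t = np.arange(0.0, 100.0, 0.05)
        m = oscillation_metrics(t, np.full_like(t, 0.4))
        assert m["amplitude"] == 0.0
        assert not m["oscillatory"]

    def test_envelope_growth_rate_on_synthetic_signal(self):
        t = np.arange(0.0, 300.0, 0.02)
        y = 1e-6 * np.exp(0.013 * t) * np.sin(0.4 * t)
        fit = envelope_growth_rate(t, y, 0.0, amp_min=1e-6, amp_max=1e-2)
        assert fit["sigma"] == pytest.approx(0.013, rel=0.02)
        assert fit["omega"] == pytest.approx(0.4, rel=0.02)
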