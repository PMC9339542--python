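"""Hydraulics: friction, resistance, steady flow, profiles, transient drain."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from dcflow import (
    Chamber,
    DeviceNetwork,
    RectChannel,
    Reservoir,
    channel_resistance,
    drain_time_constant,
    friction_coefficient,
    hydrostatic_head,
    network_resistance,
    poiseuille_profile,
    steady_flow,
    transient_drain,
)
from dcflow.hydraulics import network_from_dict, network_to_dict

from duct_oracle import exact_rect_duct_resistance


class TestFrictionCoefficient:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (1e-9, 12.0),  # parallel-plate limit
            (0.1, 12.80329),  # inlet channel aspect
            (0.05, 12.38865),  # outlet channel aspect
        ],
    )
    def test_values(self, ratio, expected):
        assert friction_coefficient(ratio) == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize("ratio", [0.0, -0.5, 1.0001, 2.0])
    def test_domain(self, ratio):
        with pytest.raises(ValueError):
            friction_coefficient(ratio)

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_bounded_below_by_plates(self, ratio):
        assert friction_coefficient(ratio) >= 12.0

    @given(
        st.floats(min_value=1e-6, max_value=0.999),
        st.floats(min_value=1e-6, max_value=1e-3),
    )
    def test_strictly_increasing(self, ratio, step):
        hi = min(ratio + step, 1.0)
        assert friction_coefficient(hi) > friction_coefficient(ratio)


class TestChannelResistance:
    def test_inlet_channel(self, reference_network):
        r = channel_resistance(reference_network.inlet_channel)
        assert r == pytest.approx(1.28033e10, rel=1e-4)

    def test_outlet_channel(self, reference_network):
        r = channel_resistance(reference_network.outlet_channel)
        assert r == pytest.approx(9.81180e11, rel=1e-4)

    def test_chamber_is_negligible(self, reference_network):
        r_ch = channel_resistance(reference_network.chamber.as_channel())
        assert r_ch == pytest.approx(1.944e8, rel=1e-3)
        assert r_ch < 1e-3 * network_resistance(reference_network)

    def test_linear_in_length(self):
        ch = RectChannel(1e-3, 1e-4, 1e-3)
        ch2 = RectChannel(1e-3, 1e-4, 2e-3)
        assert channel_resistance(ch2) == pytest.approx(2 * channel_resistance(ch), rel=1e-14)

    def test_split_channel_additivity(self):
        """Splitting a channel into sub-channels of summed length leaves the
        series resistance -- hence the flow -- unchanged."""
        whole = channel_resistance(RectChannel(1e-3, 5e-5, 9.9e-3))
        parts = channel_resistance(RectChannel(1e-3, 5e-5, 3.3e-3)) + channel_resistance(
            RectChannel(1e-3, 5e-5, 6.6e-3)
        )
        assert parts == pytest.approx(whole, rel=1e-14)

    @pytest.mark.parametrize("h_over_w", [0.02, 0.05, 0.1])
    def test_against_exact_duct_series(self, h_over_w):
        """One-term friction formula vs the full rectangular-duct series."""
        w, l = 1e-3, 1e-3
        h = h_over_w * w
        approx = channel_resistance(RectChannel(w, h, l))
        exact = exact_rect_duct_resistance(w, h, l, 1e-3)
        assert approx == pytest.approx(exact, rel=0.01)

    def test_tall_channel_rejected(self):
        with pytest.raises(ValueError, match="H <= W"):
            RectChannel(1e-4, 1e-3, 1e-3)


class TestHydrostaticHead:
    def test_twenty_microliters_in_4mm_reservoir(self):
        head = hydrostatic_head(2.0e-8, Reservoir(4.0e-3))
        assert head == pytest.approx(1.5915e-3, rel=1e-4)

    def test_zero_and_linearity(self):
        res = Reservoir(4.0e-3)
        assert hydrostatic_head(0.0, res) == 0.0
        assert hydrostatic_head(4.0e-8, res) == pytest.approx(
            2 * hydrostatic_head(2.0e-8, res), rel=1e-14
        )


class TestSteadyFlow:
    def test_reference_device_flow(self, reference_network):
        state = steady_flow(reference_network, 1.5915e-3)
        assert state.flow_rate == pytest.approx(1.5704e-11, rel=1e-3)
        assert state.chamber_mean_velocity == pytest.approx(1.298e-5, rel=1e-3)

    def test_laminar_everywhere(self, reference_network):
        state = steady_flow(reference_network, 1.5915e-3)
        for el in state.elements:
            assert el.reynolds < 1.0
            assert el.max_velocity == pytest.approx(1.5 * el.mean_velocity)

    def test_zero_head_zero_flow(self, reference_network):
        state = steady_flow(reference_network, 0.0)
        assert state.flow_rate == 0.0
        assert all(el.mean_velocity == 0.0 for el in state.elements)

    def test_network_roundtrip_through_json(self, reference_network):
        rebuilt = network_from_dict(network_to_dict(reference_network))
        assert network_resistance(rebuilt) == pytest.approx(
            network_resistance(reference_network), rel=1e-14
        )


class TestPoiseuilleProfile:
    def test_no_slip_and_peak(self):
        ch = RectChannel(1e-3, 1e-4, 1e-3)
        q = 1e-11
        mean = q / ch.cross_section
        assert poiseuille_profile(ch, q, 0.0) == 0.0
        assert poiseuille_profile(ch, q, ch.height) == 0.0
        assert poiseuille_profile(ch, q, ch.height / 2) == pytest.approx(1.5 * mean)

    def test_integrates_to_flow_rate(self):
        """Quadrature over the cross-section recovers Q to < 0.1 %."""
        ch = RectChannel(1e-3, 1e-4, 1e-3)
        q = 2.7e-11
        integral, _ = quad(lambda y: poiseuille_profile(ch, q, y) * ch.width, 0, ch.height)
        assert integral == pytest.approx(q, rel=1e-3)

    def test_out_of_gap_coordinate(self):
        ch = RectChannel(1e-3, 1e-4, 1e-3)
        with pytest.raises(ValueError):
            poiseuille_profile(ch, 1e-11, 2e-4)


class TestTransientDrain:
    def test_time_constant(self, reference_network):
        assert drain_time_constant(reference_network) == pytest.approx(636.76, rel=1e-3)

    def test_matches_exponential_closed_form(self, reference_network):
        """Euler drain vs dz0 exp(-t/tau) within 1e-3 over one time constant."""
        tau = drain_time_constant(reference_network)
        series = transient_drain(reference_network, 2.0e-8, 0.0, dt=tau / 1000, t_end=tau)
        exact = series.dz[0] * np.exp(-series.t / tau)
        rel = np.abs(series.dz - exact) / series.dz[0]
        assert rel.max() < 1e-3

    def test_first_order_convergence(self, reference_network):
        tau = drain_time_constant(reference_network)

        def err(dt):
            s = transient_drain(reference_network, 2.0e-8, 0.0, dt=dt, t_end=tau)
            return np.abs(s.dz - s.dz[0] * np.exp(-s.t / tau)).max() / s.dz[0]

        e1, e2 = err(tau / 500), err(tau / 1000)
        assert e1 / e2 == pytest.approx(2.0, rel=0.2)

    def test_conserves_total_volume(self, reference_network):
        series = transient_drain(reference_network, 2.0e-8, 5.0e-9, dt=1.0, t_end=2000.0)
        v_in = 2.0e-8 - series.V_transferred
        v_out = 5.0e-9 + series.V_transferred
        assert np.allclose(v_in + v_out, 2.5e-8, rtol=0, atol=1e-22)  # machine precision

    def test_head_decays_monotonically(self, reference_network):
        series = transient_drain(reference_network, 2.0e-8, 0.0, dt=1.0, t_end=3000.0)
        assert np.all(np.diff(series.dz) < 0)
        assert series.dz[-1] > 0

    def test_equalized_reservoirs_no_flow(self, reference_network):
        series = transient_drain(reference_network, 1.0e-8, 1.0e-8, dt=1.0, t_end=100.0)
        assert np.all(series.Q == 0.0)
        assert np.all(series.dz == 0.0)

    def test_bad_dt(self, reference_network):
        with pytest.raises(ValueError):
            transient_drain(reference_network, 1e-8, 0.0, dt=0.0, t_end=10.0)

    def test_csv_columns(self, reference_network, tmp_path):
        series = transient_drain(reference_network, 1e-8, 0.0, dt=10.0, t_end=100.0)
        path = tmp_path / "drain.csv"
        series.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "t_s,dz_m,Q_m3_per_s,V_transferred_m3"


class TestChamberGeometry:
    def test_cylindrical_floor_area(self):
        ch = Chamber(height=5e-4, shape="cylindrical", diameter=2e-3)
        assert ch.floor_area == pytest.approx(math.pi * 1e-6, rel=1e-12)

    def test_reference_chamber_volume(self, reference_chamber):
        assert reference_chamber.volume == pytest.approx(6.05e-9, rel=1e-12)

    def test_tall_narrow_chamber_maps_to_valid_channel(self):
        # chamber narrower than tall: the gap/span swap keeps H <= W
        ch = Chamber(height=5.5e-4, length=2.2e-4, width=1e-4)
        eq = ch.as_channel()
        assert eq.height <= eq.width
        assert channel_resistance(eq) > 0
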