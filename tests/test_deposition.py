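"""Sedimentation-deposition model: settling, coverage, kinetics."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dcflow import (
    CellSuspension,
    Chamber,
    DeviceNetwork,
    Reservoir,
    SeedingProtocol,
    count_at_full_coverage,
    coverage_from_count,
    deposited_count,
    deposition_curve,
    optimal_chamber_velocity,
    renewal_time,
    steady_flow,
    stokes_settling_velocity,
    time_to_coverage,
)
from dcflow.deposition import AS_PRINTED_PACKING, HEX_2D_PACKING


def _with_big_reservoirs(network: DeviceNetwork, factor: float = 1e3) -> DeviceNetwork:
    """Inflate reservoir areas so Q is effectively constant (factor on diameter)."""
    return replace(
        network,
        inlet_reservoir=Reservoir(network.inlet_reservoir.diameter * factor),
        outlet_reservoir=Reservoir(network.outlet_reservoir.diameter * factor),
    )


class TestStokesSettling:
    def test_six_micron_neuron_two_percent_excess(self):
        """Stokes velocity for the nominal cell: a=3 um, 2 % excess density."""
        v = stokes_settling_velocity(3e-6, 0.02)
        assert v == pytest.approx(3.924e-7, rel=1e-6)

    def test_neutral_buoyancy(self):
        assert stokes_settling_velocity(3e-6, 0.0) == 0.0

    def test_quadratic_in_radius(self):
        assert stokes_settling_velocity(6e-6, 0.02) == pytest.approx(
            4 * stokes_settling_velocity(3e-6, 0.02), rel=1e-12
        )


class TestOptimalChamberVelocity:
    def test_both_modes_reference_chamber(self, reference_chamber):
        assert optimal_chamber_velocity(reference_chamber, 2e-6, "as_printed") == pytest.approx(
            2.2e-7, rel=1e-9
        )
        assert optimal_chamber_velocity(reference_chamber, 2e-6, "transit_time") == pytest.approx(
            1.8182e-5, rel=1e-4
        )

    def test_modes_coincide_for_square_aspect(self):
        ch = Chamber(height=1e-3, length=1e-3, width=1e-3)
        for mode in ("as_printed", "transit_time"):
            assert optimal_chamber_velocity(ch, 2e-6, mode) == pytest.approx(2e-6)

    def test_cylinder_uses_diameter(self):
        ch = Chamber(height=5.5e-4, shape="cylindrical", diameter=5e-3)
        assert optimal_chamber_velocity(ch, 2e-6, "transit_time") == pytest.approx(
            2e-6 * 5e-3 / 5.5e-4
        )

    def test_unknown_mode(self, reference_chamber):
        with pytest.raises(ValueError, match="mode"):
            optimal_chamber_velocity(reference_chamber, 2e-6, "fastest")


class TestCoverage:
    def test_zero_cells(self):
        assert coverage_from_count(0, 3e-6, 1e-6) == 0.0

    def test_as_printed_saturates_at_packing_inverse(self):
        # raw disk-area fraction of 3 sqrt(2) / pi makes the printed form 1
        a, s = 3e-6, 1e-6
        n = (3 * math.sqrt(2) / math.pi) * s / (math.pi * a**2)
        assert coverage_from_count(n, a, s, "as_printed") == pytest.approx(1.0, rel=1e-12)

    def test_hexagonal_saturates_at_2d_hcp(self):
        a, s = 3e-6, 1e-6
        n = HEX_2D_PACKING * s / (math.pi * a**2)
        assert coverage_from_count(n, a, s, "hexagonal") == pytest.approx(1.0, rel=1e-12)

    def test_normalizations_differ_by_constant_factor(self):
        # phi_printed / phi_hexagonal = (pi/(3 sqrt 2)) / (2 sqrt 3 / pi) = pi^2/(6 sqrt 6)
        phi_p = coverage_from_count(1000, 3e-6, 1e-6, "as_printed")
        phi_h = coverage_from_count(1000, 3e-6, 1e-6, "hexagonal")
        assert phi_p / phi_h == pytest.approx(math.pi**2 / (6 * math.sqrt(6)), rel=1e-12)
        assert phi_p / phi_h == pytest.approx(AS_PRINTED_PACKING * HEX_2D_PACKING, rel=1e-12)

    def test_clipped_at_one(self):
        assert coverage_from_count(1e12, 3e-6, 1e-6) == 1.0

    def test_inverse_count(self):
        a, s = 3e-6, 2.5e-6
        for norm in ("as_printed", "hexagonal"):
            n = count_at_full_coverage(a, s, norm)
            assert coverage_from_count(n, a, s, norm) == pytest.approx(1.0, rel=1e-12)

    def test_bad_surface(self):
        with pytest.raises(ValueError):
            coverage_from_count(10, 3e-6, 0.0)


class TestDepositedCount:
    def test_reference_protocol_delivers_a_million(self):
        # 5e7 cells/mL * 20 uL
        assert deposited_count(5e13, 2e-8) == pytest.approx(1e6, rel=1e-12)

    def test_zero_volume(self):
        assert deposited_count(5e13, 0.0) == 0.0

    def test_linear_in_concentration(self):
        assert deposited_count(1.25e13, 2e-8) == pytest.approx(
            deposited_count(5e13, 2e-8) / 4, rel=1e-12
        )


class TestDepositionCurve:
    def test_count_equals_concentration_times_volume(self, reference_network, reference_protocol):
        curve = deposition_curve(reference_network, reference_protocol)
        assert np.allclose(
            curve.deposited,
            reference_protocol.suspension.number_concentration * curve.entered_volume,
            rtol=0,
            atol=0,
        )

    def test_monotonicity(self, reference_network, reference_protocol):
        curve = deposition_curve(reference_network, reference_protocol)
        assert np.all(np.diff(curve.entered_volume) >= 0)
        assert np.all(np.diff(curve.coverage) >= 0)
        assert np.all(np.diff(curve.flow_rates) <= 0)
        assert np.all(curve.coverage <= 1.0)

    def test_linear_under_constant_flow(self, reference_network, reference_suspension):
        """With inflated reservoirs Q is constant, so coverage grows linearly."""
        net = _with_big_reservoirs(reference_network)
        protocol = SeedingProtocol(reference_suspension, 2e-8 * 1e6, deposition_time=100.0)
        curve = deposition_curve(net, protocol, dt=0.5)
        phi = curve.coverage[curve.coverage < 1.0]
        t = curve.times[: len(phi)]
        slope = phi[-1] / t[-1]
        assert np.allclose(phi[1:], slope * t[1:], rtol=1e-6)

    def test_step_refinement(self, reference_network, reference_suspension):
        protocol = SeedingProtocol(reference_suspension, 2e-8, deposition_time=300.0)
        c1 = deposition_curve(reference_network, protocol, dt=1.0)
        c2 = deposition_curve(reference_network, protocol, dt=0.5)
        phi2 = np.interp(c1.times, c2.times, c2.coverage)
        mask = phi2 > 0
        assert np.max(np.abs(c1.coverage[mask] - phi2[mask]) / phi2[mask]) < 1e-3

    def test_concentration_linearity_exact(self, reference_network, reference_suspension):
        """Quarter concentration, same deposition time => exactly quarter coverage."""
        t_dep = 120.0
        full = SeedingProtocol(reference_suspension, 2e-8, deposition_time=t_dep)
        quarter = SeedingProtocol(
            replace(reference_suspension, number_concentration=1.25e13),
            2e-8,
            deposition_time=t_dep,
        )
        phi_f = deposition_curve(reference_network, full, dt=0.5).coverage[-1]
        phi_q = deposition_curve(reference_network, quarter, dt=0.5).coverage[-1]
        assert phi_q == pytest.approx(phi_f / 4, rel=1e-12)


class TestTimeToCoverage:
    def test_unreachable_when_drive_exhausted(self, reference_network, reference_suspension):
        protocol = SeedingProtocol(reference_suspension, 1e-9)  # 1 uL: tiny drive
        assert time_to_coverage(reference_network, protocol, 1.0) == math.inf

    def test_constant_q_closed_form(self, reference_network, reference_suspension):
        """t = target * S * 3 sqrt(2) / (pi^2 a^2 conc Q) in the constant-Q limit."""
        net = _with_big_reservoirs(reference_network)
        v0 = 2e-8 * 1e6
        protocol = SeedingProtocol(reference_suspension, v0)
        q0 = steady_flow(net, v0 / net.inlet_reservoir.area).flow_rate
        a = reference_suspension.cell_radius
        s = net.chamber.floor_area
        target = 0.3
        expected = target * s * 3 * math.sqrt(2) / (
            math.pi**2 * a**2 * reference_suspension.number_concentration * q0
        )
        got = time_to_coverage(net, protocol, target)
        assert got == pytest.approx(expected, rel=5e-3)

    def test_halving_flow_doubles_time(self, reference_network, reference_suspension):
        """Doubling the series resistance halves Q, doubling the time (constant-Q limit)."""
        from dcflow import channel_resistance, network_resistance

        net = _with_big_reservoirs(reference_network)
        out = net.outlet_channel
        # lengthen the outlet by exactly one total-resistance worth
        per_meter = channel_resistance(out) / out.length
        extra = network_resistance(net) / per_meter
        slow = replace(net, outlet_channel=replace(out, length=out.length + extra))
        protocol = SeedingProtocol(reference_suspension, 2e-8 * 1e6)
        t1 = time_to_coverage(net, protocol, 0.2)
        t2 = time_to_coverage(slow, protocol, 0.2)
        assert t2 / t1 == pytest.approx(2.0, rel=0.01)

    def test_target_validation(self, reference_network, reference_protocol):
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                time_to_coverage(reference_network, reference_protocol, bad)


class TestRenewalTime:
    def test_reference_chamber_turnover(self, reference_network):
        """6.05 uL chamber at 1.59 mm head turns over in ~385 s."""
        assert renewal_time(reference_network, 1.5915e-3) == pytest.approx(385.2, rel=2e-3)

    def test_inverse_in_head(self, reference_network):
        t1 = renewal_time(reference_network, 1e-3)
        t2 = renewal_time(reference_network, 2e-3)
        assert t1 / t2 == pytest.approx(2.0, rel=1e-12)

    def test_zero_head_rejected(self, reference_network):
        with pytest.raises(ValueError):
            renewal_time(reference_network, 0.0)


class TestValidation:
    def test_suspension_invariants(self):
        with pytest.raises(ValueError):
            CellSuspension(number_concentration=-1.0)
        with pytest.raises(ValueError):
            CellSuspension(number_concentration=1e13, cell_radius=0.0)

    def test_protocol_invariants(self, reference_suspension):
        with pytest.raises(ValueError):
            SeedingProtocol(reference_suspension, 0.0)
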