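"""Inverse device design: from a target cell count to a complete device.

The dimensioning procedure runs in four steps:

1. size the chamber floor so the target count corresponds to full coverage
   (inversion of the coverage normalization at phi = 1);
2. pick the chamber flow velocity matched to the cell settling velocity
   (``optimal_chamber_velocity``);
3. solve the outlet channel length that realizes that velocity under the
   hydrostatic head of the infused volume (exact algebraic inversion of the
   channel-resistance relation; inlet channel, reservoirs and channel
   cross-sections are fixed operating constraints);
4. verify by running the deterministic deposition model on the produced
   device and computing the stop-flow time at which the target is reached.

The hydrostatic drive is finite: once the free surfaces equalize only a
fraction of the infused volume has passed through the chamber.  When the
suspension volume required for the target exceeds the configured fraction
of that asymptotic transfer, the designer scales the infused volume up and
reports it; concentration is left untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .deposition import (
    AS_PRINTED_PACKING,
    HEX_2D_PACKING,
    CellSuspension,
    SeedingProtocol,
    count_at_full_coverage,
    deposition_curve,
    optimal_chamber_velocity,
    time_to_coverage,
)
from .hydraulics import (
    WATER,
    Chamber,
    DeviceNetwork,
    Fluid,
    RectChannel,
    Reservoir,
    channel_resistance,
    drain_time_constant,
    friction_coefficient,
    hydrostatic_head,
    network_resistance,
    network_to_dict,
)

__all__ = [
    "InfeasibleDesignError",
    "DesignConstraints",
    "DeviceDesign",
    "required_surface",
    "chamber_from_surface",
    "solve_outlet_length",
    "design_device",
    "partial_seeding_protocol",
]


class InfeasibleDesignError(ValueError):
    """Raised when no device satisfies the constraints; names the failing step."""

    def __init__(self, step: str, message: str):
        self.step = step
        super().__init__(f"[{step}] {message}")


@dataclass(frozen=True)
class DesignConstraints:
    """Fixed operating parameters of the design procedure.

    Defaults are the reference rectangular device: inlet channel 1000 x 100
    x 1000 um (wide and high to avoid clogging, short to limit settling in
    transit), outlet cross-section 1000 x 50 um, 4 mm reservoirs, 20 uL
    infused at 5e7 cells/mL.
    """

    inlet_channel: RectChannel = field(
        default_factory=lambda: RectChannel(1.0e-3, 1.0e-4, 1.0e-3, role="inlet")
    )
    outlet_width: float = 1.0e-3
    outlet_height: float = 5.0e-5
    inlet_reservoir_diameter: float = 4.0e-3
    outlet_reservoir_diameter: float = 4.0e-3
    infused_volume: float = 2.0e-8  # 20 uL
    suspension: CellSuspension = field(
        default_factory=lambda: CellSuspension(number_concentration=5.0e13)
    )
    chamber_aspect: tuple[float, float] = (5000.0, 2200.0)  # L_ch : W_ch
    chamber_shape: str = "rectangular"
    chamber_height: float = 5.5e-4
    velocity_mode: str = "transit_time"
    normalization: str = "as_printed"
    max_footprint: tuple[float, float] = (0.12776, 0.08548)  # ANSI/SLAS plate
    #: Required entered volume may use at most this fraction of the
    #: asymptotic reservoir-equalization transfer (keeps the stop time finite
    #: and the end-of-run flow rate non-vanishing).
    entered_volume_fraction: float = 0.8
    fluid: Fluid = WATER


def required_surface(
    target_count: float, cell_radius: float, normalization: str = "as_printed"
) -> float:
    """Chamber floor area at which ``target_count`` cells give coverage 1."""
    if target_count <= 0:
        raise ValueError("target_count must be strictly positive")
    disk = math.pi * cell_radius**2
    if normalization == "as_printed":
        return target_count * disk * AS_PRINTED_PACKING
    if normalization == "hexagonal":
        return target_count * disk / HEX_2D_PACKING
    raise ValueError(f"unknown normalization {normalization!r}")


def chamber_from_surface(surface: float, constraints: DesignConstraints) -> Chamber:
    """Realize a floor area as a chamber of the configured shape/proportions."""
    if surface <= 0:
        raise ValueError("surface must be strictly positive")
    fp_l, fp_w = constraints.max_footprint
    if constraints.chamber_shape == "cylindrical":
        d = math.sqrt(4.0 * surface / math.pi)
        if d > min(fp_l, fp_w):
            raise InfeasibleDesignError(
                "chamber_from_surface",
                f"cylindrical chamber diameter {d:.4g} m exceeds the chip footprint",
            )
        return Chamber(height=constraints.chamber_height, shape="cylindrical", diameter=d)
    a_l, a_w = constraints.chamber_aspect
    length = math.sqrt(surface * a_l / a_w)
    width = surface / length
    if length > fp_l or width > fp_w:
        raise InfeasibleDesignError(
            "chamber_from_surface",
            f"chamber {length:.4g} x {width:.4g} m exceeds the chip footprint",
        )
    return Chamber(height=constraints.chamber_height, length=length, width=width)


def _chamber_cross_section(chamber: Chamber) -> float:
    """Flow cross-section of the chamber (width across flow x height)."""
    return chamber.footprint_width * chamber.height


def solve_outlet_length(
    constraints: DesignConstraints,
    chamber: Chamber,
    infused_volume: float | None = None,
    mode: str | None = None,
) -> float:
    """Outlet channel length realizing the matched chamber velocity.

    The chamber velocity is interpreted as the mean velocity Q / (W_ch H_ch).
    With Q fixed by that velocity and the head fixed by the infused volume,
    the required total resistance follows, and the outlet length is the
    exact inversion of R = lam eta L / (W H^3) after subtracting the fixed
    elements (inlet channel and chamber).
    """
    mode = mode or constraints.velocity_mode
    v0 = infused_volume if infused_volume is not None else constraints.infused_volume
    fluid = constraints.fluid
    v_ch = optimal_chamber_velocity(chamber, constraints.suspension.settling_velocity, mode)
    q = v_ch * _chamber_cross_section(chamber)

    inlet_res = Reservoir(constraints.inlet_reservoir_diameter)
    dz0 = hydrostatic_head(v0, inlet_res)
    r_needed = fluid.density * fluid.gravity * dz0 / q
    r_fixed = channel_resistance(constraints.inlet_channel, fluid) + channel_resistance(
        chamber.as_channel(), fluid
    )
    r_out = r_needed - r_fixed
    if r_out <= 0:
        raise InfeasibleDesignError(
            "solve_outlet_length",
            f"required total resistance {r_needed:.3g} is below the fixed elements' "
            f"{r_fixed:.3g} Pa s/m^3; the target chamber velocity {v_ch:.3g} m/s "
            "cannot be reached by lengthening the outlet",
        )
    lam_out = friction_coefficient(constraints.outlet_height / constraints.outlet_width)
    return r_out * constraints.outlet_width * constraints.outlet_height**3 / (
        lam_out * fluid.viscosity
    )


@dataclass
class DeviceDesign:
    """A complete, self-consistent device plus its verification report."""

    network: DeviceNetwork
    protocol: SeedingProtocol
    target_count: float
    predicted_count: float
    report: dict

    def to_dict(self) -> dict:
        return {
            "network": network_to_dict(self.network),
            "protocol": {
                "number_concentration_per_m3": self.protocol.suspension.number_concentration,
                "cell_radius_m": self.protocol.suspension.cell_radius,
                "settling_velocity_m_per_s": self.protocol.suspension.settling_velocity,
                "infused_volume_m3": self.protocol.infused_volume,
                "deposition_time_s": self.protocol.deposition_time,
            },
            "target_count": self.target_count,
            "predicted_count": self.predicted_count,
            "report": self.report,
        }


def design_device(
    target_count: float, constraints: DesignConstraints | None = None
) -> DeviceDesign:
    """Run the full four-step dimensioning chain for a target cell count."""
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    c = constraints if constraints is not None else DesignConstraints()
    susp = c.suspension
    conc = susp.number_concentration
    if conc <= 0:
        raise InfeasibleDesignError("design_device", "suspension concentration is zero")

    surface = required_surface(target_count, susp.cell_radius, c.normalization)
    chamber = chamber_from_surface(surface, c)

    # Scale the infused volume if the drive cannot deliver the target.
    v_req = target_count / conc
    a_in = math.pi * c.inlet_reservoir_diameter**2 / 4.0
    a_out = math.pi * c.outlet_reservoir_diameter**2 / 4.0
    transfer_ratio = a_out / (a_in + a_out)  # asymptotic transfer / infused
    infused = c.infused_volume
    if v_req > c.entered_volume_fraction * transfer_ratio * infused:
        infused = v_req / (c.entered_volume_fraction * transfer_ratio)

    l_out = solve_outlet_length(c, chamber, infused_volume=infused)
    network = DeviceNetwork(
        inlet_reservoir=Reservoir(c.inlet_reservoir_diameter),
        inlet_channel=c.inlet_channel,
        chamber=chamber,
        outlet_channel=RectChannel(c.outlet_width, c.outlet_height, l_out, role="outlet"),
        outlet_reservoir=Reservoir(c.outlet_reservoir_diameter),
        fluid=c.fluid,
    )
    protocol = SeedingProtocol(susp, infused)
    stop_time = time_to_coverage(network, protocol, 1.0, normalization=c.normalization)
    if not math.isfinite(stop_time):
        raise InfeasibleDesignError(  # pragma: no cover - prevented by scaling above
            "design_device", "full coverage unreachable with the scaled drive"
        )
    protocol = replace(protocol, deposition_time=stop_time)

    curve = deposition_curve(network, protocol, normalization=c.normalization)
    predicted = float(curve.deposited[-1])

    v_ch_modes = {
        m: optimal_chamber_velocity(chamber, susp.settling_velocity, m)
        for m in ("transit_time", "as_printed")
    }
    l_out_modes: dict[str, float | None] = {}
    for m in ("transit_time", "as_printed"):
        try:
            l_out_modes[m] = solve_outlet_length(c, chamber, infused_volume=infused, mode=m)
        except InfeasibleDesignError:
            l_out_modes[m] = None

    dz0 = hydrostatic_head(infused, network.inlet_reservoir)
    report = {
        "surface_m2": surface,
        "chamber": {
            "shape": chamber.shape,
            "height_m": chamber.height,
            "length_m": chamber.footprint_length,
            "width_m": chamber.footprint_width,
        },
        "velocity_mode": c.velocity_mode,
        "velocity_convention": "chamber mean velocity Q / (W_ch * H_ch)",
        "v_ch_m_per_s": v_ch_modes,
        "q_initial_m3_per_s": v_ch_modes[c.velocity_mode] * _chamber_cross_section(chamber),
        "total_resistance_pa_s_per_m3": network_resistance(network),
        "l_out_m": l_out,
        "l_out_by_mode_m": l_out_modes,
        "dz0_m": dz0,
        "tau_s": drain_time_constant(network),
        "infused_volume_m3": infused,
        "infused_volume_scaled": infused != c.infused_volume,
        "stop_time_s": stop_time,
        "stop_instruction": (
            f"equalize reservoir volumes at t = {stop_time:.1f} s "
            "(top up the outlet or withdraw the imbalance)"
        ),
        "normalization": c.normalization,
        "predicted_over_target": predicted / target_count,
    }
    return DeviceDesign(network, protocol, target_count, predicted, report)


def partial_seeding_protocol(
    design: DeviceDesign, target_coverage: float
) -> tuple[SeedingProtocol, float]:
    """Protocol reaching a partial coverage at the *same* deposition time.

    The deposited count is exactly linear in the suspension concentration at
    fixed flow history, so scaling the concentration by the target coverage
    and keeping the stop time unchanged yields that coverage.  The
    alternative strategy -- keep the concentration, stop the flow early --
    is returned as the second element (its stop time).
    """
    if not 0.0 < target_coverage <= 1.0:
        raise ValueError("target_coverage must lie in (0, 1]")
    susp = design.protocol.suspension
    scaled = replace(susp, number_concentration=susp.number_concentration * target_coverage)
    protocol = replace(design.protocol, suspension=scaled)
    stop_early = time_to_coverage(
        design.network,
        design.protocol,
        target_coverage,
        normalization=design.report.get("normalization", "as_printed"),
    )
    return protocol, stop_early
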