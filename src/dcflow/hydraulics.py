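"""Pressure-driven laminar flow through a series deposition-chamber device.

A deposition-chamber (DC) device is a strict series circuit:

    inlet reservoir -> inlet channel -> deposition chamber -> outlet channel
    -> outlet reservoir

There is no pump.  Flow is driven purely by the hydrostatic head ``dz`` --
the free-surface height difference between the two open cylindrical
reservoirs.  All channels operate at Reynolds numbers well below one, so the
pressure drop over each shallow rectangular channel is a linear (Hagen--
Poiseuille type) resistance

    R = lam * eta * L / (W * H**3),      lam = 12 / (1 - 6 (2/pi)**5 H/W)

and the instantaneous flow rate is ``Q = rho g dz / sum(R)``.  Minor losses
at cross-section changes are neglected: at these flow rates they are orders
of magnitude below the channel friction.

As fluid moves from inlet to outlet the free surfaces converge, so the head
decays.  ``transient_drain`` integrates this quasi-static drain with an
explicit Euler step; for constant-section reservoirs the exact solution is
an exponential with time constant

    tau = sum(R) / (rho * g * (1/A_in + 1/A_out)).

All quantities are strict SI (m, s, kg, Pa).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Fluid",
    "WATER",
    "RectChannel",
    "Chamber",
    "Reservoir",
    "DeviceNetwork",
    "ElementFlow",
    "FlowState",
    "TransientSeries",
    "PROFILE_FACTOR",
    "friction_coefficient",
    "channel_resistance",
    "network_resistance",
    "hydrostatic_head",
    "steady_flow",
    "poiseuille_profile",
    "drain_time_constant",
    "transient_drain",
    "network_to_dict",
    "network_from_dict",
    "load_network",
    "save_network",
]

#: Ratio of the peak to the mean velocity of a plane Poiseuille profile.
PROFILE_FACTOR = 1.5

_CHANNEL_ROLES = ("inlet", "outlet", "microchannel", "chamber")


@dataclass(frozen=True)
class Fluid:
    """Newtonian working fluid; defaults are water at room temperature."""

    density: float = 1000.0  # kg/m^3
    viscosity: float = 1.0e-3  # Pa s
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        for name in ("density", "viscosity", "gravity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Fluid.{name} must be strictly positive")


WATER = Fluid()


@dataclass(frozen=True)
class RectChannel:
    """Shallow rectangular channel of width W, height H and length L.

    The friction model used throughout assumes H <= W (parallel-plate
    regime); the constructor enforces it.
    """

    width: float
    height: float
    length: float
    role: str = "microchannel"

    def __post_init__(self) -> None:
        for name in ("width", "height", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RectChannel.{name} must be strictly positive")
        if self.height > self.width:
            raise ValueError(
                "RectChannel requires H <= W (shallow-channel friction model); "
                f"got H={self.height} > W={self.width}"
            )
        if self.role not in _CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")

    @property
    def cross_section(self) -> float:
        return self.width * self.height

    @property
    def hydraulic_diameter(self) -> float:
        return 2.0 * self.width * self.height / (self.width + self.height)


@dataclass(frozen=True)
class Chamber:
    """Deposition chamber: a tall, wide open compartment the cells settle in.

    ``shape`` is ``"rectangular"`` (length along the flow, width across it)
    or ``"cylindrical"`` (a disk of the given diameter).
    """

    height: float
    shape: str = "rectangular"
    length: float | None = None
    width: float | None = None
    diameter: float | None = None

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("Chamber.height must be strictly positive")
        if self.shape == "rectangular":
            if self.length is None or self.width is None:
                raise ValueError("rectangular Chamber needs length and width")
            if self.length <= 0 or self.width <= 0:
                raise ValueError("Chamber dimensions must be strictly positive")
        elif self.shape == "cylindrical":
            if self.diameter is None or self.diameter <= 0:
                raise ValueError("cylindrical Chamber needs a positive diameter")
        else:
            raise ValueError(f"unknown chamber shape {self.shape!r}")

    @property
    def floor_area(self) -> float:
        """Bottom (deposition) surface S."""
        if self.shape == "rectangular":
            return self.length * self.width
        return math.pi * self.diameter**2 / 4.0

    @property
    def volume(self) -> float:
        return self.floor_area * self.height

    @property
    def footprint_length(self) -> float:
        """Extent along the flow direction (L_ch, or D_ch for a disk)."""
        return self.length if self.shape == "rectangular" else self.diameter

    @property
    def footprint_width(self) -> float:
        """Extent across the flow direction (W_ch, or D_ch for a disk)."""
        return self.width if self.shape == "rectangular" else self.diameter

    def as_channel(self) -> RectChannel:
        """Hydraulic stand-in for resistance purposes.

        The chamber contributes negligibly to the series resistance (its
        smallest dimension is an order of magnitude above the channels'), so
        it is modelled as a rectangular channel.  A cylindrical chamber maps
        to an equivalent square of side D.  The smaller transverse dimension
        always plays the role of the plate gap, so tall narrow chambers stay
        inside the H <= W domain of the friction formula.
        """
        if self.shape == "rectangular":
            w, l = self.width, self.length
        else:
            w = l = self.diameter
        gap, span = (self.height, w) if self.height <= w else (w, self.height)
        return RectChannel(width=span, height=gap, length=l, role="chamber")


@dataclass(frozen=True)
class Reservoir:
    """Open cylindrical reservoir with a flat free surface."""

    diameter: float
    fluid_volume: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("Reservoir.diameter must be strictly positive")
        if self.fluid_volume < 0:
            raise ValueError("Reservoir.fluid_volume must be non-negative")

    @property
    def area(self) -> float:
        return math.pi * self.diameter**2 / 4.0

    @property
    def free_surface_height(self) -> float:
        return self.fluid_volume / self.area


@dataclass(frozen=True)
class DeviceNetwork:
    """The series hydraulic unit: reservoir, channel, chamber, channel, reservoir."""

    inlet_reservoir: Reservoir
    inlet_channel: RectChannel
    chamber: Chamber
    outlet_channel: RectChannel
    outlet_reservoir: Reservoir
    fluid: Fluid = WATER

    def channel_elements(self) -> list[tuple[str, RectChannel]]:
        """Resistive elements in series order, chamber as its hydraulic stand-in."""
        return [
            ("inlet_channel", self.inlet_channel),
            ("chamber", self.chamber.as_channel()),
            ("outlet_channel", self.outlet_channel),
        ]


def friction_coefficient(h_over_w: float) -> float:
    """Low-Reynolds friction coefficient of a shallow rectangular channel.

    lam = 12 * (1 - 6 (2/pi)^5 (H/W))**-1.  Tends to 12 (parallel plates)
    as H/W -> 0 and is restricted to 0 < H/W <= 1: the denominator changes
    sign near H/W ~ 1.594, outside the model's regime.
    """
    if not 0.0 < h_over_w <= 1.0:
        raise ValueError(f"friction_coefficient requires 0 < H/W <= 1, got {h_over_w}")
    return 12.0 / (1.0 - 6.0 * (2.0 / math.pi) ** 5 * h_over_w)


def channel_resistance(channel: RectChannel, fluid: Fluid = WATER) -> float:
    """Hydrodynamic resistance R = lam eta L / (W H^3) in Pa s / m^3.

    Equivalently the head loss is ``dz = R Q / (rho g)``.
    """
    lam = friction_coefficient(channel.height / channel.width)
    return lam * fluid.viscosity * channel.length / (channel.width * channel.height**3)


def network_resistance(network: DeviceNetwork) -> float:
    """Total series resistance of the device (channels + chamber)."""
    return sum(channel_resistance(ch, network.fluid) for _, ch in network.channel_elements())


def hydrostatic_head(infused_volume: float, reservoir: Reservoir) -> float:
    """Free-surface rise caused by infusing a volume into a cylindrical reservoir."""
    if infused_volume < 0:
        raise ValueError("infused_volume must be non-negative")
    return infused_volume / reservoir.area


@dataclass(frozen=True)
class ElementFlow:
    name: str
    mean_velocity: float
    max_velocity: float
    reynolds: float


@dataclass(frozen=True)
class FlowState:
    """Steady solution: one flow rate shared by every series element."""

    head_difference: float
    flow_rate: float
    elements: tuple[ElementFlow, ...]

    @property
    def chamber_mean_velocity(self) -> float:
        for el in self.elements:
            if el.name == "chamber":
                return el.mean_velocity
        raise KeyError("no chamber element in FlowState")


def steady_flow(network: DeviceNetwork, head_difference: float) -> FlowState:
    """Solve the series network at a fixed head difference.

    Q = rho g dz / sum(R); per-element mean velocity Q/(W H), peak velocity
    1.5x the mean (plane Poiseuille), Reynolds number on the hydraulic
    diameter.
    """
    if head_difference < 0:
        raise ValueError("head_difference must be non-negative")
    fluid = network.fluid
    total_r = network_resistance(network)
    q = fluid.density * fluid.gravity * head_difference / total_r
    elements = []
    for name, ch in network.channel_elements():
        v = q / ch.cross_section
        re = fluid.density * v * ch.hydraulic_diameter / fluid.viscosity
        elements.append(ElementFlow(name, v, PROFILE_FACTOR * v, re))
    return FlowState(head_difference, q, tuple(elements))


def poiseuille_profile(channel: RectChannel, flow_rate: float, height_coordinate: float) -> float:
    """Plane Poiseuille velocity at height y above the channel floor.

    v(y) = 6 (Q/(W H)) (y/H)(1 - y/H): parabolic across the gap, uniform
    across the width, integrating back to Q over the cross-section.
    """
    h = channel.height
    if not 0.0 <= height_coordinate <= h:
        raise ValueError(f"height_coordinate must lie in [0, {h}]")
    u = height_coordinate / h
    return 6.0 * (flow_rate / channel.cross_section) * u * (1.0 - u)


def drain_time_constant(network: DeviceNetwork) -> float:
    """Exponential time constant tau = sum(R) / (rho g (1/A_in + 1/A_out))."""
    fluid = network.fluid
    inv_a = 1.0 / network.inlet_reservoir.area + 1.0 / network.outlet_reservoir.area
    return network_resistance(network) / (fluid.density * fluid.gravity * inv_a)


@dataclass
class TransientSeries:
    """Time series of a hydrostatic drain (or any quasi-static run)."""

    t: np.ndarray
    dz: np.ndarray
    Q: np.ndarray
    V_transferred: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "dz_m": self.dz,
                "Q_m3_per_s": self.Q,
                "V_transferred_m3": self.V_transferred,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def transient_drain(
    network: DeviceNetwork,
    initial_inlet_volume: float,
    initial_outlet_volume: float,
    dt: float,
    t_end: float,
) -> TransientSeries:
    """Explicit-Euler quasi-static drain of the reservoir imbalance.

    At each step a volume ``Q dt`` moves from the inlet to the outlet
    reservoir and the head is recomputed from both free surfaces.  Total
    fluid volume is conserved exactly (a single transfer variable is
    stepped).  As dt -> 0 the head converges (first order) to
    ``dz0 * exp(-t/tau)``.  A head inversion (outlet above inlet) simply
    reverses the sign of Q; the scheme is symmetric.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if initial_inlet_volume < 0 or initial_outlet_volume < 0:
        raise ValueError("initial reservoir volumes must be non-negative")

    fluid = network.fluid
    a_in = network.inlet_reservoir.area
    a_out = network.outlet_reservoir.area
    total_r = network_resistance(network)
    rho_g = fluid.density * fluid.gravity

    n = max(1, int(round(t_end / dt)))
    t = np.arange(n + 1) * dt
    dz = np.empty(n + 1)
    q = np.empty(n + 1)
    v_x = np.empty(n + 1)

    x = 0.0  # cumulative volume moved inlet -> outlet
    for i in range(n + 1):
        head = (initial_inlet_volume - x) / a_in - (initial_outlet_volume + x) / a_out
        flow = rho_g * head / total_r
        dz[i] = head
        q[i] = flow
        v_x[i] = x
        if i < n:
            x += flow * dt
    return TransientSeries(t=t, dz=dz, Q=q, V_transferred=v_x)


# ---------------------------------------------------------------------------
# JSON (de)serialization of device geometry, SI units throughout.


def network_to_dict(network: DeviceNetwork) -> dict:
    ch = network.chamber
    chamber: dict = {"shape": ch.shape, "height": ch.height}
    if ch.shape == "rectangular":
        chamber.update(length=ch.length, width=ch.width)
    else:
        chamber.update(diameter=ch.diameter)
    return {
        "fluid": {
            "density": network.fluid.density,
            "viscosity": network.fluid.viscosity,
            "gravity": network.fluid.gravity,
        },
        "inlet_reservoir": {
            "diameter": network.inlet_reservoir.diameter,
            "fluid_volume": network.inlet_reservoir.fluid_volume,
        },
        "inlet_channel": {
            "width": network.inlet_channel.width,
            "height": network.inlet_channel.height,
            "length": network.inlet_channel.length,
        },
        "chamber": chamber,
        "outlet_channel": {
            "width": network.outlet_channel.width,
            "height": network.outlet_channel.height,
            "length": network.outlet_channel.length,
        },
        "outlet_reservoir": {
            "diameter": network.outlet_reservoir.diameter,
            "fluid_volume": network.outlet_reservoir.fluid_volume,
        },
    }


def network_from_dict(doc: dict) -> DeviceNetwork:
    try:
        fluid = Fluid(**doc.get("fluid", {}))
        inlet_res = Reservoir(**doc["inlet_reservoir"])
        outlet_res = Reservoir(**doc["outlet_reservoir"])
        inlet_ch = RectChannel(role="inlet", **doc["inlet_channel"])
        outlet_ch = RectChannel(role="outlet", **doc["outlet_channel"])
        chamber = Chamber(**doc["chamber"])
    except KeyError as exc:
        raise ValueError(f"device document missing section {exc}") from exc
    return DeviceNetwork(inlet_res, inlet_ch, chamber, outlet_ch, outlet_res, fluid)


def load_network(path) -> DeviceNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def save_network(network: DeviceNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=2, sort_keys=True)
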