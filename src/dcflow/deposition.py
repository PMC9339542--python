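"""Deterministic sedimentation-deposition model for cell seeding.

Cells in suspension enter the deposition chamber with the pumpless flow and
settle onto the floor at their sedimentation velocity.  The design-point
model assumes every cell entering the chamber deposits, so the deposited
count is simply ``N(t) = phi_c * V(t)`` where ``phi_c`` is the suspension
number concentration and ``V(t)`` the suspension volume that has entered the
chamber (the cumulative transferred volume of the hydrostatic drain).

The floor coverage is normalized so 1 means maximal packing of the
monolayer.  Two conventions are shipped:

* ``"as_printed"``:   phi = (N pi a^2 / S) * pi / (3 sqrt 2)
  -- the published form, whose constant pi/(3 sqrt 2) ~ 0.7405 is the
  *three*-dimensional close-packing fraction;
* ``"hexagonal"``:    phi = (N pi a^2 / S) / (pi / (2 sqrt 3))
  -- reaches 1 exactly at the 2D hexagonal close packing of disks
  (area fraction pi/(2 sqrt 3) ~ 0.9069), the physically attainable
  monolayer maximum.

The two differ by the constant factor 2/sqrt(6) ~ 0.8165.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hydraulics import (
    WATER,
    Chamber,
    DeviceNetwork,
    Fluid,
    drain_time_constant,
    steady_flow,
    transient_drain,
)

__all__ = [
    "AS_PRINTED_PACKING",
    "HEX_2D_PACKING",
    "CellSuspension",
    "SeedingProtocol",
    "CoverageSeries",
    "stokes_settling_velocity",
    "optimal_chamber_velocity",
    "coverage_from_count",
    "count_at_full_coverage",
    "deposited_count",
    "deposition_curve",
    "time_to_coverage",
    "renewal_time",
]

#: Constant of the published coverage normalization (3D close-packing fraction).
AS_PRINTED_PACKING = math.pi / (3.0 * math.sqrt(2.0))
#: Area fraction of 2D hexagonal close packing of equal disks.
HEX_2D_PACKING = math.pi / (2.0 * math.sqrt(3.0))

_NORMALIZATIONS = ("as_printed", "hexagonal")


@dataclass(frozen=True)
class CellSuspension:
    """Cell suspension: number concentration (cells/m^3), cell radius and
    settling velocity.

    The default settling velocity of 2 um/s is the published design value
    for dissociated neurons.  Note that a Stokes computation with the same
    nominal parameters (6 um diameter, 2 % excess density) yields ~0.39
    um/s; both routes are exposed and the discrepancy is documented rather
    than resolved (see docs/methods.md).
    """

    number_concentration: float  # cells / m^3
    cell_radius: float = 3.0e-6  # m
    settling_velocity: float = 2.0e-6  # m/s
    excess_density_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.number_concentration < 0:
            raise ValueError("number_concentration must be non-negative")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be strictly positive")
        if self.settling_velocity <= 0:
            raise ValueError("settling_velocity must be strictly positive")


@dataclass(frozen=True)
class SeedingProtocol:
    """Seeding protocol: what is infused into the inlet reservoir and for
    how long the flow is allowed to run before it is stopped by equalizing
    the reservoirs (``deposition_time``; ``None`` = run to full coverage or
    to flow stop)."""

    suspension: CellSuspension
    infused_volume: float  # m^3
    deposition_time: float | None = None  # s

    def __post_init__(self) -> None:
        if self.infused_volume <= 0:
            raise ValueError("infused_volume must be strictly positive")
        if self.deposition_time is not None and self.deposition_time < 0:
            raise ValueError("deposition_time must be non-negative")


def stokes_settling_velocity(
    cell_radius: float, excess_density_fraction: float, fluid: Fluid = WATER
) -> float:
    """Terminal velocity of a sphere of radius a denser than the fluid by the
    given fraction: v = 2 a^2 (drho) g / (9 eta)."""
    if cell_radius <= 0:
        raise ValueError("cell_radius must be strictly positive")
    if excess_density_fraction < 0:
        raise ValueError("excess_density_fraction must be non-negative")
    drho = excess_density_fraction * fluid.density
    return 2.0 * cell_radius**2 * drho * fluid.gravity / (9.0 * fluid.viscosity)


def optimal_chamber_velocity(
    chamber: Chamber, settling_velocity: float, mode: str = "transit_time"
) -> float:
    """Chamber flow velocity matched to the cell settling velocity.

    The design criterion is that a cell entering at the top of the chamber
    reaches the floor just before reaching the exit, i.e. the settling time
    H/V_sedi equals the transit time L/V_ch:

    * ``"transit_time"``:  V_ch = V_sedi * L_ch / H_ch  (the criterion solved
      for V_ch; the package default);
    * ``"as_printed"``:    V_ch = V_sedi * H_ch / L_ch  (the published
      formula verbatim, retained for reproduction).

    For a cylindrical chamber the diameter replaces L_ch.
    """
    if settling_velocity <= 0:
        raise ValueError("settling_velocity must be strictly positive")
    l_ref = chamber.footprint_length
    if mode == "as_printed":
        return settling_velocity * chamber.height / l_ref
    if mode == "transit_time":
        return settling_velocity * l_ref / chamber.height
    raise ValueError(f"unknown mode {mode!r}; use 'as_printed' or 'transit_time'")


def coverage_from_count(
    count: float,
    cell_radius: float,
    surface: float,
    normalization: str = "as_printed",
) -> float:
    """Floor coverage phi in [0, 1] of ``count`` cells on surface S."""
    if surface <= 0:
        raise ValueError("surface must be strictly positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    raw = count * math.pi * cell_radius**2 / surface
    if normalization == "as_printed":
        phi = raw * AS_PRINTED_PACKING
    elif normalization == "hexagonal":
        phi = raw / HEX_2D_PACKING
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return min(1.0, phi)


def count_at_full_coverage(
    cell_radius: float, surface: float, normalization: str = "as_printed"
) -> float:
    """Cell count at which the coverage normalization reaches exactly 1."""
    if surface <= 0:
        raise ValueError("surface must be strictly positive")
    disk = math.pi * cell_radius**2
    if normalization == "as_printed":
        return surface / (disk * AS_PRINTED_PACKING)
    if normalization == "hexagonal":
        return surface * HEX_2D_PACKING / disk
    raise ValueError(f"unknown normalization {normalization!r}")


def deposited_count(concentration: float, entered_volume: float) -> float:
    """N = phi_c * V: cells carried into the chamber by the entered volume.

    Continuous (fractional cells allowed); round only at reporting time.
    """
    if concentration < 0 or entered_volume < 0:
        raise ValueError("concentration and entered_volume must be non-negative")
    return concentration * entered_volume


@dataclass
class CoverageSeries:
    """Time-resolved seeding state under the transient hydrostatic drive."""

    times: np.ndarray
    flow_rates: np.ndarray
    entered_volume: np.ndarray
    deposited: np.ndarray
    coverage: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.times,
                "Q_m3_per_s": self.flow_rates,
                "V_m3": self.entered_volume,
                "N_cells": self.deposited,
                "phi": self.coverage,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _initial_volumes(network: DeviceNetwork, protocol: SeedingProtocol) -> tuple[float, float]:
    """Reservoir contents at t=0: the infused suspension sits on top of any
    base volume in the inlet; the outlet keeps its base volume."""
    v_in = network.inlet_reservoir.fluid_volume + protocol.infused_volume
    v_out = network.outlet_reservoir.fluid_volume
    return v_in, v_out


def _initial_head(network: DeviceNetwork, protocol: SeedingProtocol) -> float:
    v_in, v_out = _initial_volumes(network, protocol)
    return v_in / network.inlet_reservoir.area - v_out / network.outlet_reservoir.area


def _asymptotic_transfer(network: DeviceNetwork, protocol: SeedingProtocol) -> float:
    """Volume that has entered the chamber once the free surfaces equalize."""
    dz0 = _initial_head(network, protocol)
    inv_a = 1.0 / network.inlet_reservoir.area + 1.0 / network.outlet_reservoir.area
    return max(0.0, dz0 / inv_a)


def deposition_curve(
    network: DeviceNetwork,
    protocol: SeedingProtocol,
    dt: float | None = None,
    normalization: str = "as_printed",
) -> CoverageSeries:
    """Couple the transient drain with the deposition model.

    Every cell that enters the chamber is assumed to deposit (the design
    point), so ``N = phi_c * V`` holds exactly at every sample and the
    coverage is the (clipped) normalized disk area of N cells.  The series
    ends at the protocol's ``deposition_time`` if given, otherwise at full
    coverage or -- if neither is reached -- after ten drain time constants,
    by which point the flow has effectively stopped.
    """
    susp = protocol.suspension
    s_floor = network.chamber.floor_area
    n_cap = count_at_full_coverage(susp.cell_radius, s_floor, normalization)
    tau = drain_time_constant(network)

    if protocol.deposition_time is not None:
        t_end = protocol.deposition_time
    else:
        t_full = time_to_coverage(network, protocol, 1.0, normalization=normalization)
        t_end = min(10.0 * tau, 1.05 * t_full) if math.isfinite(t_full) else 10.0 * tau
    if dt is None:
        dt = tau / 1000.0
        if t_end > 0:
            dt = min(dt, t_end / 200.0)
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    t_end = max(t_end, dt)

    v_in0, v_out0 = _initial_volumes(network, protocol)
    series = transient_drain(network, v_in0, v_out0, dt, t_end)
    entered = series.V_transferred
    deposited = susp.number_concentration * entered
    coverage = np.minimum(1.0, deposited / n_cap) if n_cap > 0 else np.zeros_like(deposited)

    if protocol.deposition_time is None:
        full = np.nonzero(coverage >= 1.0)[0]
        if full.size:
            stop = full[0] + 1
            return CoverageSeries(
                series.t[:stop],
                series.Q[:stop],
                entered[:stop],
                deposited[:stop],
                coverage[:stop],
            )
    return CoverageSeries(series.t, series.Q, entered, deposited, coverage)


def time_to_coverage(
    network: DeviceNetwork,
    protocol: SeedingProtocol,
    target: float,
    normalization: str = "as_printed",
) -> float:
    """Smallest t with coverage(t) >= target; ``math.inf`` if unreachable.

    Unreachable means the drive (the reservoir imbalance) or the protocol's
    time window is exhausted before the target coverage: the free surfaces
    equalize after transferring a finite volume, capping the cell supply.
    The closed-form exponential drain supplies a first estimate which is
    then refined on the explicit-Euler series.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError("target coverage must lie in (0, 1]")
    susp = protocol.suspension
    conc = susp.number_concentration
    if conc <= 0:
        return math.inf
    n_req = target * count_at_full_coverage(susp.cell_radius, network.chamber.floor_area, normalization)
    v_req = n_req / conc
    v_inf = _asymptotic_transfer(network, protocol)
    if v_req >= v_inf:
        return math.inf

    tau = drain_time_constant(network)
    t_closed = -tau * math.log1p(-v_req / v_inf)
    if protocol.deposition_time is not None and t_closed > protocol.deposition_time:
        return math.inf
    if t_closed == 0.0:
        return 0.0

    # Refine on the discrete series the rest of the package integrates.
    dt = t_closed / 1000.0
    v_in0, v_out0 = _initial_volumes(network, protocol)
    series = transient_drain(network, v_in0, v_out0, dt, 1.5 * t_closed)
    idx = np.nonzero(series.V_transferred >= v_req)[0]
    if idx.size == 0:  # pragma: no cover - safety margin exceeded
        return math.inf
    i = idx[0]
    if i == 0:
        return 0.0
    v0, v1 = series.V_transferred[i - 1], series.V_transferred[i]
    frac = (v_req - v0) / (v1 - v0) if v1 > v0 else 1.0
    t = series.t[i - 1] + frac * dt
    if protocol.deposition_time is not None and t > protocol.deposition_time:
        return math.inf
    return float(t)


def renewal_time(network: DeviceNetwork, head: float) -> float:
    """One-turnover estimate of fluid exchange: chamber volume / Q(head)."""
    if head <= 0:
        raise ValueError("head must be strictly positive for a renewal estimate")
    q = steady_flow(network, head).flow_rate
    return network.chamber.volume / q
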