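"""Stochastic particle-level simulator of advection plus sedimentation.

Each simulated particle stands for a fixed number of cells.  A particle
enters the chamber at a random height (by default flux-weighted: the
probability of arriving at height y is proportional to the local Poiseuille
velocity there), advects horizontally at the local, time-varying chamber
velocity while settling vertically at the suspension's sedimentation
velocity, and is recorded where it first touches the floor.  Particles that
reach the far end of the chamber before touching down are counted as exited.

The simulator exists to answer the spatial questions the deterministic
model cannot: where on the floor the cells land, how uniform the resulting
layer is across four quarters or ten flow-perpendicular sections, and how
close real capture is to the 100 %-capture design assumption.

Entry *times* are sampled in proportion to the instantaneous flow rate of
the transient drain, so the cumulative entered-particle count reproduces
``N = phi_c * V(t)`` of the deterministic model in expectation; the landing
times additionally carry the sedimentation delay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deposition import SeedingProtocol, coverage_from_count
from .hydraulics import Chamber, DeviceNetwork, drain_time_constant, transient_drain

__all__ = [
    "SimulationConfig",
    "DepositionMap",
    "simulate_deposition",
    "section_counts",
    "section_series",
    "quarter_counts",
    "quarter_series",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_particles: int = 10_000
    dt: float | None = None  # s; default resolves the settling time in 50 steps
    seed: int = 0
    entry_sampling: str = "flux_weighted"  # or "uniform"
    #: Entry-height reduction modelling settling inside the inlet channel
    #: (0 by default: the short inlet is designed to make it negligible).
    inlet_settling_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.entry_sampling not in ("flux_weighted", "uniform"):
            raise ValueError(f"unknown entry_sampling {self.entry_sampling!r}")
        if self.inlet_settling_offset < 0:
            raise ValueError("inlet_settling_offset must be non-negative")


@dataclass
class DepositionMap:
    """Per-particle landing record of one simulation.

    ``x`` runs along the flow from the chamber entrance, ``y`` across the
    flow; both are landing coordinates of the particles that touched down.
    ``entry_times`` covers *all* injected particles (landed and exited).
    ``cell_weight`` converts particle counts to cell counts.
    """

    x: np.ndarray
    y: np.ndarray
    t_land: np.ndarray
    t_entry: np.ndarray
    entry_times: np.ndarray
    exited_count: int
    n_injected: int
    cell_weight: float
    seed: int
    chamber_length: float
    chamber_width: float

    @property
    def landed_count(self) -> int:
        return self.x.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"x_m": self.x, "y_m": self.y, "t_s": self.t_land}).to_csv(
            path, index=False
        )

    def sidecar(self) -> dict:
        return {
            "seed": self.seed,
            "n_injected": self.n_injected,
            "landed": int(self.landed_count),
            "exited_count": self.exited_count,
            "cell_weight": self.cell_weight,
            "chamber_length_m": self.chamber_length,
            "chamber_width_m": self.chamber_width,
        }

    def save_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2, sort_keys=True)


def _flux_weighted_heights(r: np.ndarray) -> np.ndarray:
    """Invert the flux CDF C(u) = 3u^2 - 2u^3 of the parabolic profile."""
    grid = np.linspace(0.0, 1.0, 4097)
    cdf = 3.0 * grid**2 - 2.0 * grid**3
    return np.interp(r, cdf, grid)


def _chord_width(chamber: Chamber, x: np.ndarray) -> np.ndarray:
    """Local width across the flow at position x (chord for a disk)."""
    if chamber.shape == "rectangular":
        return np.full_like(x, chamber.width)
    r = chamber.diameter / 2.0
    chord = 2.0 * np.sqrt(np.maximum(r**2 - (x - r) ** 2, 0.0))
    # Keep the 1D quasi-uniform approximation finite at the rims.
    return np.maximum(chord, 0.1 * r)


def simulate_deposition(
    network: DeviceNetwork,
    protocol: SeedingProtocol,
    config: SimulationConfig = SimulationConfig(),
) -> DepositionMap:
    """Monte Carlo advection-sedimentation run; bit-reproducible per seed."""
    chamber = network.chamber
    h = chamber.height
    length = chamber.footprint_length
    v_sedi = protocol.suspension.settling_velocity
    settle_time = h / v_sedi

    dt = config.dt if config.dt is not None else settle_time / 50.0
    if settle_time < 10.0 * dt:
        raise ValueError(
            f"dt={dt} too coarse to resolve settling (need H/V_sedi >= 10 dt, "
            f"H/V_sedi = {settle_time})"
        )

    tau = drain_time_constant(network)
    t_flow_end = protocol.deposition_time if protocol.deposition_time is not None else 10.0 * tau
    v_in0 = network.inlet_reservoir.fluid_volume + protocol.infused_volume
    v_out0 = network.outlet_reservoir.fluid_volume
    dt_drain = min(tau / 1000.0, t_flow_end / 200.0)
    drain = transient_drain(network, v_in0, v_out0, dt_drain, t_flow_end)
    v_total = float(drain.V_transferred[-1])

    n = config.n_particles
    rng = np.random.default_rng(config.seed)
    # Entry times: uniform in entered volume <=> flux-weighted in time.
    t_entry = np.interp(rng.random(n) * v_total, drain.V_transferred, drain.t)
    r_height = rng.random(n)
    if config.entry_sampling == "flux_weighted":
        u0 = _flux_weighted_heights(r_height)
    else:
        u0 = r_height
    y_height = np.maximum(u0 * h - config.inlet_settling_offset, 1e-12)
    lat_frac = rng.random(n)  # lateral position as a fraction of the local width

    x = np.zeros(n)
    status = np.zeros(n, dtype=np.int8)  # 0 pending, 1 active, 2 landed, 3 exited
    x_land = np.full(n, np.nan)
    t_land = np.full(n, np.nan)

    def q_at(t: float) -> float:
        if t >= drain.t[-1]:
            return 0.0 if protocol.deposition_time is not None else float(drain.Q[-1])
        return float(np.interp(t, drain.t, drain.Q))

    t = 0.0
    t_max = float(t_entry.max()) + settle_time + 2.0 * dt
    while t < t_max and np.any(status < 2):
        status[(status == 0) & (t_entry < t + dt)] = 1
        active = status == 1
        if not active.any():
            # nothing in flight: jump the clock to the next entry
            pending = t_entry[status == 0]
            if pending.size == 0:
                break
            t += max(dt, math.floor((pending.min() - t) / dt) * dt)
            continue
        if active.any():
            # Per-particle effective step: particles entering mid-step only
            # advance over the remainder of the step.
            dt_i = np.clip(t + dt - np.maximum(t_entry[active], t), 0.0, dt)
            q_mid = q_at(t + 0.5 * dt)
            w_loc = _chord_width(chamber, x[active])
            u = y_height[active] / h
            vx = 6.0 * (q_mid / (w_loc * h)) * u * (1.0 - u)
            dx = vx * dt_i
            dy = v_sedi * dt_i

            y_new = y_height[active] - dy
            x_new = x[active] + dx
            idx = np.nonzero(active)[0]

            touch = y_new <= 0.0
            with np.errstate(divide="ignore", invalid="ignore"):
                f_land = np.where(dy > 0, y_height[active] / dy, np.inf)
                f_exit = np.where(dx > 0, (length - x[active]) / dx, np.inf)
            lands = touch & (f_land <= f_exit)
            exits = (x_new >= length) & ~lands

            li = idx[lands]
            x_land[li] = x[li] + dx[lands] * f_land[lands]
            t_land[li] = np.maximum(t_entry[li], t) + f_land[lands] * dt_i[lands]
            status[li] = 2

            ei = idx[exits]
            status[ei] = 3

            move = idx[~lands & ~exits]
            keep = ~lands & ~exits
            x[move] = x_new[keep]
            y_height[move] = y_new[keep]
        t += dt

    landed = status == 2
    exited_count = int(np.count_nonzero(status == 3))
    w_land = _chord_width(chamber, x_land[landed])
    if chamber.shape == "rectangular":
        y_lat = lat_frac[landed] * w_land
    else:
        r = chamber.diameter / 2.0
        y_lat = r + (lat_frac[landed] - 0.5) * w_land

    conc = protocol.suspension.number_concentration
    cell_weight = conc * v_total / n if n else 0.0
    order = np.argsort(t_land[landed], kind="stable")
    return DepositionMap(
        x=x_land[landed][order],
        y=y_lat[order],
        t_land=t_land[landed][order],
        t_entry=t_entry[landed][order],
        entry_times=np.sort(t_entry),
        exited_count=exited_count,
        n_injected=n,
        cell_weight=cell_weight,
        seed=config.seed,
        chamber_length=length,
        chamber_width=chamber.footprint_width,
    )


def _section_areas(chamber: Chamber, n_sections: int) -> np.ndarray:
    """Floor areas of equal-width slices perpendicular to the flow."""
    length = chamber.footprint_length
    edges = np.linspace(0.0, length, n_sections + 1)
    if chamber.shape == "rectangular":
        return np.full(n_sections, chamber.floor_area / n_sections)
    r = chamber.diameter / 2.0

    def cum(xv: np.ndarray) -> np.ndarray:
        s = np.clip((xv - r) / r, -1.0, 1.0)
        return r**2 * (np.arcsin(s) + s * np.sqrt(1.0 - s**2)) + r**2 * math.pi / 2.0

    c = cum(edges)
    return np.diff(c)


def section_counts(dmap: DepositionMap, n_sections: int) -> np.ndarray:
    """Cells landed per flow-perpendicular section (section 1 at the inlet)."""
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    edges = np.linspace(0.0, dmap.chamber_length, n_sections + 1)
    counts, _ = np.histogram(np.clip(dmap.x, 0.0, dmap.chamber_length), bins=edges)
    return counts * dmap.cell_weight


def section_series(
    dmap: DepositionMap,
    chamber: Chamber,
    n_sections: int = 10,
    times: np.ndarray | None = None,
    normalization: str = "as_printed",
    cell_radius: float = 3.0e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-section coverage over time: (times, coverage[len(times), n_sections])."""
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if times is None:
        t_hi = float(dmap.t_land.max()) if dmap.t_land.size else 1.0
        times = np.linspace(0.0, t_hi, 50)
    edges = np.linspace(0.0, dmap.chamber_length, n_sections + 1)
    areas = _section_areas(chamber, n_sections)
    sec = np.clip(np.digitize(dmap.x, edges) - 1, 0, n_sections - 1)
    cov = np.zeros((len(times), n_sections))
    for i, t in enumerate(times):
        landed = dmap.t_land <= t
        for k in range(n_sections):
            n_cells = np.count_nonzero(landed & (sec == k)) * dmap.cell_weight
            cov[i, k] = coverage_from_count(n_cells, cell_radius, areas[k], normalization)
    return np.asarray(times), cov


def quarter_counts(dmap: DepositionMap, chamber: Chamber) -> np.ndarray:
    """Cells per quarter, split by the flow axis and its perpendicular.

    Order: [inlet-left, inlet-right, outlet-left, outlet-right], where
    "inlet" means the half nearer the chamber entrance and left/right is
    across the flow.
    """
    cx = chamber.footprint_length / 2.0
    cy = chamber.footprint_width / 2.0
    inlet_half = dmap.x < cx
    left_half = dmap.y < cy
    counts = np.array(
        [
            np.count_nonzero(inlet_half & left_half),
            np.count_nonzero(inlet_half & ~left_half),
            np.count_nonzero(~inlet_half & left_half),
            np.count_nonzero(~inlet_half & ~left_half),
        ],
        dtype=float,
    )
    return counts * dmap.cell_weight


def quarter_series(
    dmap: DepositionMap,
    chamber: Chamber,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative cell counts per quarter over time: (times, counts[:, 4])."""
    if times is None:
        t_hi = float(dmap.t_land.max()) if dmap.t_land.size else 1.0
        times = np.linspace(0.0, t_hi, 50)
    cx = chamber.footprint_length / 2.0
    cy = chamber.footprint_width / 2.0
    quarter = 2 * (dmap.x >= cx).astype(int) + (dmap.y >= cy).astype(int)
    out = np.zeros((len(times), 4))
    for i, t in enumerate(times):
        landed = dmap.t_land <= t
        for k in range(4):
            out[i, k] = np.count_nonzero(landed & (quarter == k)) * dmap.cell_weight
    return np.asarray(times), out
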