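# Methods

## Hydraulic model

A deposition-chamber device is a strict series circuit — inlet reservoir,
inlet channel, chamber, outlet channel, outlet reservoir — driven only by
the hydrostatic head `dz` between the two open reservoirs. Every channel
operates at Reynolds numbers far below one, so each shallow rectangular
channel is a linear resistance

```
R = lam * eta * L / (W H^3),   lam = 12 (1 - 6 (2/pi)^5 (H/W))^-1
```

and `Q = rho g dz / sum(R)`. The one-term friction coefficient `lam` is
the low-aspect approximation of the exact rectangular-duct double series;
for the aspect ratios the devices use (H/W ≤ 0.25) it agrees with the
exact series to better than 1 % (the exact series is kept in the test
suite as an independent oracle, never in the production path). `lam` is
restricted to 0 < H/W ≤ 1 because its denominator changes sign near
H/W ≈ 1.594; channels are constructed with H ≤ W, and a chamber narrower
than it is tall is mapped to its hydraulic stand-in with the smaller
transverse dimension as the plate gap.

Assumptions and simplifications:

- **Minor losses neglected.** Pressure drops at cross-section changes are
  orders of magnitude below channel friction at these flow rates; the
  solver exposes no hook for them.
- **Chamber as a wide channel.** The chamber's hydraulic resistance
  (~2×10⁸ Pa s/m³ for the reference chamber) is negligible against the
  channels (~10¹²); cylindrical chambers use an equivalent square of side
  D. The approximation error is irrelevant at three orders of magnitude
  below the outlet resistance.
- **Plane Poiseuille profile.** Velocity is parabolic across the gap and
  uniform across the width; the peak/mean factor is fixed at 1.5. This is
  consistent with the shallow-channel regime of `lam`; the full
  rectangular-duct profile is not used.
- **Ideal cylindrical reservoirs** with flat free surfaces; meniscus and
  capillary effects are ignored.

### Transient drain

As volume moves from inlet to outlet the head decays. `transient_drain`
steps the quasi-static balance with explicit Euler (a single transfer
variable, so total volume is conserved to machine precision). For
constant-section reservoirs the exact solution is
`dz(t) = dz0 exp(-t/tau)` with
`tau = sum(R) / (rho g (1/A_in + 1/A_out))`; the Euler series converges to
it at first order, with relative error `~ (t/tau)(dt/2tau)` — below 10⁻³
over one time constant at the default `dt = tau/1000`. Equal reservoir
volumes give `Q = 0` identically: stop-flow is modelled as equalizing the
reservoirs.

## Deposition model

Cells are treated as non-interacting spheres of radius `a = 3 µm`
settling at `V_sedi`. Two values of `V_sedi` coexist deliberately:

- the **default, 2 µm/s**, is the published design value for dissociated
  neurons and is what the designer uses;
- the **Stokes route**, `v = 2 a^2 (drho) g / (9 eta)`, gives ≈ 0.39 µm/s
  for the same nominal cell (6 µm diameter, 2 % excess density).

The two are inconsistent by a factor ≈ 5; the package exposes both and
does not resolve the discrepancy (cell aggregation during seeding would
push the effective value up, but that is speculation — the default simply
reproduces the established design point).

The design-point model assumes **100 % capture**: every cell entering the
chamber deposits, so `N(t) = c · V(t)` with `V(t)` the entered (drained)
volume, and coverage is

```
phi = (N pi a^2 / S) * pi/(3 sqrt 2)        ("as_printed", default)
phi = (N pi a^2 / S) / (pi/(2 sqrt 3))      ("hexagonal")
```

both clipped at 1. The default constant `pi/(3 sqrt 2) ≈ 0.7405` is the
*three*-dimensional close-packing fraction; with it, `phi = 1` corresponds
to a raw disk-area fraction of `3√2/π ≈ 1.35`, which is geometrically
impossible for a monolayer. The `hexagonal` normalization instead reaches
1 exactly at the 2D hexagonal close packing of disks (area fraction
`π/(2√3) ≈ 0.9069`). The printed form is kept as the default for
fidelity to the established design procedure; designers wanting physical
consistency switch per call. The two differ by the constant factor
`π²/(6√6) ≈ 0.6715`.

### Matched chamber velocity

The matching criterion — a cell entering at the ceiling reaches the floor
just before the chamber exit — equates the settling time `H/V_sedi` with
the transit time `L/V_ch`, giving `V_ch = V_sedi · L/H`
(**transit_time**, the default). The printed formula of the source design
procedure has the ratio inverted (`V_ch = V_sedi · H/L`,
**as_printed**); it is retained verbatim as an option and both are
reported by the designer, because the two differ by (L/H)² ≈ 80 for the
reference chamber and the printed outlet length is bracketed by the two
conventions. `V_ch` is interpreted as the chamber *mean* velocity
`Q/(W_ch H_ch)` throughout.

With the parabolic profile, the transit-time matching has an exact
property the simulator confirms: a cell entering at height `y0` lands at
`x = L · C(y0/H)` where `C(u) = 3u² - 2u³` is precisely the flux CDF, so
flux-weighted arrivals under a steady drive land *uniformly* along the
chamber, and the cell entering exactly at the ceiling is the marginal
(measure-zero) escape case.

## Monte Carlo simulator

Each particle stands for `c·V_total/n` cells. Entry times are sampled
uniformly in entered volume (flux-weighted in time), entry heights from
the parabolic flux profile (or uniformly, for sensitivity checks), lateral
positions uniformly across the width. Particles advect at the local,
time-varying parabolic velocity, settle at `V_sedi`, and are recorded
where they touch the floor; crossing the far end first counts as exited.
Landing is located by sub-step linear interpolation. The time step must
resolve settling (`H/V_sedi ≥ 10 dt`; default 50 steps per settling time).

The deterministic model books a cell as deposited *on entry*; the
simulator's entered-particle count is therefore the observable that
matches `N = c·V(t)` (binomially distributed around it), while landing
times additionally carry the sedimentation delay. Both are exposed on the
`DepositionMap`.

Not modelled: Brownian motion (Péclet numbers are enormous for 6 µm
cells), lateral dispersion, resuspension or rolling after touchdown,
cell–wall hydrodynamics. Settling inside the short inlet channel is
ignored by default (an entry-height offset can represent it). Cylindrical
chambers use a 1D quasi-uniform chord approximation for the local
velocity.

## Inverse designer

Four steps, each an exact algebraic inversion:

1. `required_surface`: floor area at which the target count gives
   coverage 1 (inversion of the normalization);
2. `chamber_from_surface`: realize the area at the configured aspect
   ratio (default 5000:2200, the reference chamber's) or as a disk;
3. `solve_outlet_length`: with `Q` fixed by the matched velocity and the
   head by the infused volume, subtract the fixed elements' resistance and
   invert `R(L)` for the outlet length;
4. verification: `time_to_coverage(phi=1)` on the transient model gives
   the stop-flow time, and a deterministic re-simulation confirms the
   reached count (≥ 95 % of target is the round-trip test band; in
   practice the model round-trips to ~0.1 %).

**Finite-drive correction.** The drain only transfers
`V0 · A_out/(A_in + A_out)` before the free surfaces equalize, so a
million-cell target cannot be fed by the default 20 µL at 5×10⁷ cells/mL.
When the required entered volume exceeds 0.8 of the asymptotic transfer,
the designer scales the infused volume up (concentration is never
touched) and flags it in the report. The 0.8 headroom keeps the stop time
near 1.6 τ and the end-of-run flow rate non-vanishing; it was fixed once
as a design constant.

Fixed operating constraints default to the reference device: inlet
channel 1000×100×1000 µm, outlet cross-section 1000×50 µm, 4 mm
reservoirs, 20 µL infusion, 5×10⁷ cells/mL. Outlet lengths for small
targets come out at tens of centimetres to metres — they would be routed
as serpentines; the chip-footprint check applies to the chamber, not to
channel routing.

Partial seeding scales the concentration by the target coverage at an
unchanged deposition time (the model is exactly linear in concentration);
the alternative stop-early time is reported for comparison.

## Circuit-to-chip translation

A circuit descriptor (`dcflow-circuit/1`) is a JSON object with `nodes`
(unique names, target cell counts, optional region volumes) and directed
`edges` (microchannel arrays, default 450 µm long). Validation collects
*all* violations with JSON-pointer paths. The schema is defined by this
package; the packaged example is the basal ganglia direct pathway
(Cortex → Striatum → GPi/SNr → Thalamus → Cortex, with SNc → Striatum)
with per-region counts from a rat-brain volumetric table.

`translate` is deterministic: one inverse-designed chamber per node,
placed left-to-right in the topological order of the condensed graph
(declaration order inside cycles and for ties), on the centre line of an
ANSI/SLAS microplate footprint (127.76 × 85.48 mm); reservoirs snap to
the nearest free well of the 9 mm pitch grid (A1 at 14.38, 11.24 mm);
edges become straight arrays between chamber borders, with endpoints
clamped to each chamber's border span. Automatic placement optimization
is out of scope — `validate_layout` re-checks every invariant (overlap,
grid snap, footprint, edge realization, electrode totals) so hand-edited
layouts can be iterated against the same rules.

`allocate_electrodes` apportions the MEA's electrodes (default 256) to
chambers proportionally to floor area with largest-remainder rounding
(total exact, per-node deviation < 1), then places each node's share on a
uniform rectangular sub-grid of its chamber. Nodes whose area share
rounds to zero receive no electrode — with the basal ganglia counts the
cortex chamber dominates the area, which is a faithful consequence of
area-proportional allocation.

## Image quantification

`synth_nuclei_image` renders one filled disk per landed cell plus Gaussian
background noise (defaults: foreground 1.0, background 0.1, σ = 0.05 —
a clean bimodal separation typical of DAPI nuclei on dark background) and
records the ground truth (count, disk-union coverage, nominal disk-area
fraction) in the provenance. What the generator does **not** emulate:
illumination gradients, out-of-focus blur, intensity variation between
nuclei, debris. A green closure test therefore establishes that the
measurement pipeline is unbiased on well-posed images, not that it is
robust to real-microscope artefacts.

Thresholding is a single global Otsu threshold (deterministic, logged),
replacing the operator-dependent per-tile brightness adjustment of manual
pipelines. If the two Otsu classes differ by less than four pooled
standard deviations the image is treated as unimodal background — without
this guard Otsu splits pure noise in half.

Counting (`estimate_count`, mode `components`) assigns each connected
foreground component `max(1, round(1 + (A/m - 1)/0.75))` nuclei, `m`
being the mean nucleus area: two disks whose centres fall within one
diameter (uniformly distributed) overlap by exactly `m/4` in expectation,
so each disk merged into a cluster adds ~0.75 m of union area. Isolated
nuclei are counted exactly; components below `m/4` are discarded as noise
specks. The plain area quotient (`mode="area"`) is kept for reference; it
is biased low by ~9 % at 20 % coverage, which is why the corrected
estimator is the default. Homogeneity reports give per-section counts and
coverages, measured/expected ratios (expected = total/n under the
uniformity null), quarter counts, and a 10×10 tile coverage matrix (each
tile a hundredth of the image).

## Numerical conventions

- SI units everywhere internally; conversions only at I/O boundaries.
- Explicit Euler for all transients; `dt = tau/1000` by default, refined
  automatically near short stop times; time-to-coverage interpolates the
  crossing linearly between steps.
- Fractional cell counts are carried throughout; rounding only at
  reporting.
- Seeded `numpy` Generators everywhere; identical seeds give bit-identical
  maps and images.
- Statistical tests on section uniformity use Bonferroni-corrected bands
  (ten simultaneous comparisons).

## Known limitations

- The deterministic model's 100 % capture means it cannot represent
  under-seeding from cells washing through; the Monte Carlo simulator can
  (exited particles), but at matched velocity the exit fraction is ~0.
- Deposition windows longer than a fraction of τ, or stop-flow while many
  cells are airborne, skew the landing profile toward the inlet; the
  uniformity guarantees hold in the steady-drive regime
  (settling time ≪ window ≪ τ).
- The full-coverage cap is a hard clip: no surface exclusion or crowding
  below `phi = 1`.
- No CFD: entrance effects, corner flows and 3D velocity fields are
  outside the model.
- Measured peak velocities reported for devices of this class are not
  reproduced quantitatively by the printed geometry under any single
  velocity convention; the package treats them as qualitative anchors
  only.
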