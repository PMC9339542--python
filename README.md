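# dcflow

Design and simulation of **pumpless microfluidic deposition chambers** —
the plating compartments used in brain-on-chip devices to seed a chosen
number of neurons, uniformly, into each node of an engineered neural
circuit.

A deposition chamber (DC) sits between an inlet and an outlet channel fed
by open reservoirs. There is no pump: infusing a volume into the inlet
reservoir raises its free surface by `dz = V / (pi D^2 / 4)`, and the flow
through the series network is

```
Q = rho g dz / sum(R),     R = lam * eta * L / (W H^3),
lam = 12 / (1 - 6 (2/pi)^5 (H/W))
```

for each shallow rectangular channel (Re < 1 everywhere). Cells entering
the chamber settle at their sedimentation velocity `V_sedi` while being
carried at the chamber velocity `V_ch = Q / (W_ch H_ch)`; matching
`V_ch = V_sedi * L_ch / H_ch` makes a cell entering at the ceiling touch
down right at the end of the chamber, which is what produces a uniform
monolayer. The deposited count is `N(t) = c * V(t)` (suspension
concentration times entered volume) and the floor coverage is the
normalized disk area `phi = (N pi a^2 / S) * pi/(3 sqrt 2)`, clipped at 1.

The package provides:

- `dcflow.hydraulics` — resistances, steady flow, plane-Poiseuille
  profiles, and the explicit-Euler hydrostatic drain
  (`dz(t) -> dz0 e^(-t/tau)`);
- `dcflow.deposition` — Stokes settling, matched chamber velocity,
  coverage kinetics, time-to-coverage, fluid renewal time;
- `dcflow.particle_sim` — a seeded Monte Carlo advection–sedimentation
  simulator producing spatial deposition maps, with four-quarter and
  ten-section uniformity series;
- `dcflow.designer` — inverse design: target cell count → chamber size,
  outlet length, seeding protocol and stop-flow time, verified by
  re-simulation;
- `dcflow.circuit` — JSON circuit descriptors (`dcflow-circuit/1`), chip
  layout generation on the ANSI/SLAS microplate grid, MEA electrode
  allocation, layout validation and SVG rendering. A five-node basal
  ganglia direct-pathway circuit ships as the worked example;
- `dcflow.quantify` — synthetic nuclei images, tiled threshold coverage,
  overlap-corrected nucleus counting, homogeneity reports.

## Worked example

```python
>>> from dcflow import design_device, deposition_curve
>>> design = design_device(100_000)          # one hundred thousand neurons
>>> r = design.report
>>> print(f"chamber {r['chamber']['length_m']*1e3:.2f} x "
...       f"{r['chamber']['width_m']*1e3:.2f} mm, "
...       f"L_out = {r['l_out_m']*1e3:.1f} mm, stop at {r['stop_time_s']:.0f} s")
chamber 2.18 x 0.96 mm, L_out = 37.5 mm, stop at 533 s
>>> curve = deposition_curve(design.network, design.protocol)
>>> print(f"deposited {curve.deposited[-1]:.0f} cells, coverage {curve.coverage[-1]:.3f}")
deposited 99987 cells, coverage 1.000
```

The designer sized a 2.18 × 0.96 mm chamber (the floor that holds 1e5
cells at full packing-normalized coverage), solved a 37.5 mm outlet
channel so the chamber runs at its matched velocity under the 20 µL
hydrostatic head, and instructs the operator to stop the flow — by
equalizing the reservoir volumes — at t ≈ 533 s, at which point the
deterministic model confirms 99 987 cells (> 99.9 % of target) on the
floor.

Translating a circuit into a chip:

```sh
dcflow design --target-cells 1e5 --out design.json
dcflow translate bg5.json --electrodes 256 --out layout.json --svg layout.svg
dcflow simulate design.json --particles 10000 --seed 1 --out map.csv
dcflow quantify nuclei.tif --chamber design.json --pixel-size 0.5e-6
```

## Acceptance script

`scripts/acceptance.py` re-runs the main computation chain from scratch —
the reference-device hydraulics, the 1e3–1e6 design family with their
deterministic round trips, a seeded Monte Carlo deposition with its
render-and-requantify closure, and the five-node basal ganglia chip
translation — and writes its JSON output to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

The model, its assumptions, numerical choices and known limitations are
described in [docs/methods.md](docs/methods.md).
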