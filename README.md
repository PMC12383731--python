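# stentflow

Desk-scale computational hemodynamics of intracranial aneurysms treated
with braided flow-diverter stents (FDS), built around a **local-density
porous model (LDPM)**: instead of meshing every 30 µm wire of the deployed
device, the braid is replaced by a thin cylindrical shell whose flow
resistance varies cell by cell with the local wire density. The package is
for researchers and students in vascular CFD who want a transparent,
dependency-light reference implementation of the screen-resistance
approach — virtual braid deployment, porous-coefficient assembly, a steady
incompressible finite-volume solver, a wire-resolved validation oracle, and
the standard aneurysm metrics — on idealized geometries that run in minutes
on one CPU.

## The model

A deployed braid forms rhombic cells. For each cell the pipeline computes
the total area `A_t`, wire area `A_w`, porosity

    ε = A_p / A_t = (A_t − A_w) / A_t,

braiding angle `α` and hydraulic diameter `D_h`, and converts them into the
woven-screen pressure loss

    Δp = −(ρ/2)·[1.3(1−ε) + (1/ε−1)²]·v² − 11·μ·v / D_h

at through-shell velocity `v`. The loss acts as a momentum sink
`Δp / t` over the shell thickness `t = 2·d_w = 60 µm`, opposing only the
shell-normal velocity component. Deployment kinematics (inextensible
counter-rotating helical wire families, crossing conservation) make the
resistance respond to the vessel: compression below nominal diameter
elongates the device and opens its pores; curvature packs cells on the
inner curve and spreads them on the outer curve. Coil-assisted treatment
adds an isotropic Darcy–Forchheimer region in the sac parameterized by the
volume embolization ratio (VER). Scenario outcomes are summarized by four
metrics — sac mean velocity, wall mean shear rate, neck inflow rate, and
turnover time (sac volume / inflow) — and compared with the relative change
`X_RE = (X_variant − X_baseline)/X_baseline × 100 %`.

## Worked example

```bash
stentflow run straight_sidewall -o out/
```

runs the bundled sidewall-aneurysm fixture end to end (4 mm parent vessel,
2.5 mm dome, 48-wire device at 4.5 mm nominal diameter, blood at
ρ = 1100 kg/m³, inlet mass flow 0.003465 kg/s) and prints:

```
mean_velocity: 0.00979836
mean_shear_rate: 27.0435
inflow_rate: 3.36859e-06
turnover_time: 5.61659
sac_volume: 1.892e-05
```

Units are SI; the fixture is a planar slice, so values are per meter of
depth — directions and relative changes between scenarios are the
meaningful outputs, not absolute patient-scale numbers. Removing the stent
(`stentflow run untreated_sidewall`) raises the inflow rate by ~20%,
the device's purpose in reverse. Other subcommands: `scenario` (resized /
repositioned / coil-assisted variants with change rates against the
baseline), `grid-dep` (porous-region grid study), `oracle-compare`
(resolved cylinder screen vs the correlation), `export-field` (VTK/CSV
artifacts). Every run writes a manifest (config hash, seed, versions) and
is bit-reproducible from its config.

The same pipeline is available as a library:

```python
from stentflow import (StentDesign, make_straight_vessel, deploy_stent,
                       extract_cells)
design = StentDesign(n_wires=48, nominal_diameter=4.5e-3, nominal_length=10e-3)
vessel = make_straight_vessel(radius=2e-3, length=0.08, spacing=2.5e-4)
cells = extract_cells(deploy_stent(design, vessel, start_position=5e-3))
print(f"mean porosity {sum(c.porosity for c in cells)/len(cells):.3f}")
# mean porosity 0.790   (vs 0.654 at nominal diameter: oversizing opens pores)
```

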