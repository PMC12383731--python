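# Methods

`stentflow` models the hemodynamic effect of a braided flow-diverter stent
(FDS) on a sidewall aneurysm with a *local-density porous model* (LDPM): the
deployed braid is replaced by a thin shell of spatially varying screen
resistance derived from the local wire density, so the flow solver never has
to resolve 30 µm wires. This note records the models, the assumptions, the
defaults, and what the desk-scale fixtures do and do not demonstrate.

## Braid deployment kinematics

A device of `n` wires (half per handedness) is treated as an inextensible
braid lying on the lumen surface. Let `alpha` be the between-wire angle at
the axial vertex of a rhombus cell (default `alpha_0 = 150°` at the nominal
diameter: FDS wires run nearly circumferentially, which is what produces
their high metal coverage). Each wire advances along the surface at angle
`alpha/2` from the local axis. Two constraints close the model:

* **Crossing conservation.** Consecutive crossings along a wire are fixed
  wire-length `s_cell` apart, and `n/2` rhombi tile the circumference:
  `s_cell * sin(alpha/2) = 2*pi*R/n`. Radial constraint to a radius below
  nominal therefore *lowers* `alpha` (clipped to `(0.05π, 0.95π)`): wires
  turn axial, the device elongates, and — because cell area
  `A_t = s² sin(alpha)` grows as `alpha` scissors toward 90° — porosity
  *increases*. This is the well-known oversizing effect (an oversized device
  in a small vessel gives lower metal coverage), and it holds for any
  `alpha_0 > 90°`; a hypothetical low-angle braid (`alpha_0 < 90°`) would
  densify instead. The porosity property test asserts the `alpha_0 > 90°`
  direction, which is the clinically relevant one.
* **Equal wire-length advancement.** Wires advance in equal wire-length
  steps; mapping the (arc-position, angle) lattice onto a curved centerline
  compresses the pattern on the inner curve and stretches it on the outer
  curve. No contact mechanics or friction is modelled; per-wire length is
  conserved to well under 0.5% by construction (verified on straight and
  curved vessels).

Crossings fall on rings of `n/2` points; cells are indexed by (ring, sector)
so extraction is exact rather than a root-finding search. Per cell the
geometry yields total area `A_t` (3D quadrilateral of its four crossings),
wire area `A_w = perimeter/2 · d_w − d_w²/sin(alpha)` (strip area with the
crossing-overlap parallelogram removed once — each cell owns four
quarter-crossings), porosity `ε = (A_t − A_w)/A_t` and hydraulic diameter
`D_h`. The closed-form flat-braid porosity `(1 − d_w/(s·sin alpha))²` and a
pixel-rasterization oracle agree with the extracted values to <2%. Only
complete rhombi are generated by the ring lattice, so no special end-cell
patching is needed.

## Screen resistance and the shell

The pressure loss across one braid cell follows the woven-screen
correlation

    Δp = −(ρ/2)·[1.3(1−ε) + (1/ε − 1)²]·v² − 11·μ·v/D_h

with `v` the through-screen (shell-normal) velocity. Quadratic and linear
coefficients `C2 = (ρ/2)[..]` and `C1 = 11μ/D_h` are attached per braid
cell and mapped to solver cells in the shell (thickness `t = 2·d_w = 60 µm`,
reflecting wire overlap at crossings) by nearest-centroid lookup in
surface coordinates (KD-tree on `(s, R·cosθ, R·sinθ)`).

Two readings of the hydraulic-diameter definition are provided because the
printed form (`D_h = A_t · sin alpha`) is dimensionally inconsistent if
`A_t` is an area: `verbatim` (default) reads the symbol as the cell side
length, giving `s·sin alpha`; `pore_hydraulic` computes `4A_p/P_p` of the
open rhombic pore, which equals `(s − d_w/sin alpha)·sin alpha` and
coincides with `verbatim` in the thin-wire limit. An `intersections_zero`
toggle (default off) zeroes the resistance within one wire diameter of
crossing loci for sensitivity studies; it is off by default because
crossings are where the braid is densest.

The jump becomes a per-volume momentum sink `S = Δp(ε, D_h, v_n)/t_layer`
over the resolved shell layer. The layer is at least one grid layer thick
and `t_layer` is the actually-marked thickness per normal column, which
makes the *integrated* pressure jump independent of how many grid layers
span the shell — verified to machine precision on a uniform duct. In the
vessel fixtures the layer sits on the lumen side of the wall line (a
wall-apposed device lives inside the lumen, not in the sac). The sink
opposes only the shell-normal velocity component; tangential flow is
unresisted, as screen physics dictates (an isotropic option is not provided
— the coil region covers the isotropic case).

Inside the solver the sink force is evaluated from the *face-interpolated*
normal velocity with a deferred correction (the implicit, diagonal part
uses the cell velocity for stability). Collocated cell velocities are not
mass-conserving across a one-cell-thick momentum jump; using the
face-based through-flow keeps the integrated jump exact even for a
single-layer shell.

## Coil region

Coil packing is an isotropic Darcy–Forchheimer sink over the packed part of
the sac: porosity `φ = 1 − VER` (volume embolization ratio = coil volume /
aneurysm volume), permeability from the Kozeny–Carman relation
`k = φ³ d_c²/(180(1−φ)²)` with the coil wire diameter `d_c = 0.25 mm` as
grain size, and an Ergun inertial coefficient `1.75ρ(1−φ)/(d_c φ³)`. This is
a stand-in for bespoke coil-resistance correlations, adequate for direction
and ordering studies at small VER. The workbench places the coil region
above the dome equator: coils settle in the fundus, and the neck plane —
where inflow and turnover are measured, upstream of the coils — stays
coil-free. With coil resistance extended all the way to the neck plane the
neck exchange is throttled directly and the neck metrics lose their
upstream character; the clearance is configurable
(`CoilConfig.neck_clearance_fraction`).

## Flow solver

Steady incompressible Navier–Stokes, finite volume on a uniform collocated
grid, 2D planar or 2D axisymmetric, with stair-step masked solid cells.
SIMPLE pressure–velocity coupling with Rhie–Chow face interpolation;
convection is second-order central via deferred correction on an implicit
first-order upwind stencil (pure upwind available; its numerical diffusion
`~ρ·u·h/2` exceeds the physical viscosity at the default cell sizes and
visibly damps the sac recirculation). Under-relaxation is fixed at 0.7
(momentum) / 0.3 (pressure) so runs are deterministic; convergence requires
normalized momentum and continuity residuals below 1e-6 (solver default;
the workbench fixtures use 1e-5, which changes the sac metrics by well
under the grid-level differences) within 10,000 outer iterations, else the
field is flagged unconverged and case runs abort nonzero. Sparse systems
are solved directly (scipy). Boundary conditions follow the standard
analysis setup: prescribed inlet mass flow with a fully developed profile,
0 Pa static outlet, rigid no-slip walls (slip/symmetry available; the
axisymmetric axis is always a symmetry line). Outlet face fluxes are
rescaled each outer iteration so global mass balance holds to better than
1e-3 at convergence.

Validation: planar Poiseuille at 40 cells across agrees with the analytic
profile to <0.1%; axisymmetric Hagen–Poiseuille to <2% at 30 radial cells;
the uniform porous duct reproduces the screen correlation to ~1e-8.

## Fixtures: what they emulate

The bundled cases are desk-scale planar analogues, not patient anatomy:

* **straight_sidewall** — a 32 mm channel of height 4 mm (the 2R of a 2 mm
  radius tube) with a spherical-cap sac (dome radius 2.5 mm, neck radius
  1.25 mm) on the wall; the 3D braid is deployed on the corresponding
  tube and its cell coefficients are projected onto the channel's wall line
  at the sac side (θ = 0). Inlet mass flow 0.003465 kg/s on the tube is
  converted to the planar channel so the *mean velocity* (~0.25 m/s,
  diastolic internal-carotid conditions, ρ = 1100 kg/m³, μ = 3.6 mPa·s
  Newtonian default with a pluggable shear-rate-dependent law) is
  preserved; Reynolds number ~300, laminar.
* **curved_sidewall** — the same pipeline on a 90° bend (bend radius
  12 mm), exercising the inner/outer-curve density asymmetry; the solver
  runs on the straightened (arc-length) channel, so the curvature enters
  through the wire density only.
* **duct + uniform screen** — slip-walled duct with a prescribed-(ε, D_h)
  transverse shell; the consistency and refinement workbench.

Because the fixtures are 2D slices, absolute metric values (sac mean
velocity, wall shear rate, inflow, turnover) are *not* comparable to 3D
patient numbers; directions, orderings and relative changes are the
quantities the tests assert. A stented neck reduces inflow by ~17% on the
fixture; VER = 1.2%/2.4% coil packing reduces sac mean velocity
monotonically while changing neck inflow by <2%.

## Wire-resolved oracle

The accuracy reference is a row of explicitly resolved cylinders spanning a
slip-walled (periodic-equivalent) channel, solved on a fine masked grid
(≥8 cells per wire diameter; 10 used in the shipped checks) by the same
solver. At matching open-area fraction and gap scale (`D_h` = gap) the
screen correlation and the resolved pressure drop agree within a factor of
two across ε ∈ {0.6, 0.7, 0.8} at gap Reynolds ≤ 50 (superficial velocity
0.2 m/s); observed ratios are ≈0.75–1.0. The resolved field also shows the
gap jetting (local acceleration between wires) that any porous
representation smooths out — the known, accepted locality error of screen
models.

## Grid-dependence harness

Such studies vary the porous-region resolution while the bulk mesh stays
fixed; the harness mirrors that: `mode="shell"` re-runs the case with the
shell resistance resolved over widths {0.8, 0.4, 0.2, 0.1} mm on the fixed
fixture grid (the integrated jump is invariant by construction; what
converges is where the momentum is removed). Sac mean velocity changes by
<1% between the two finest levels. `mode="grid"` refines both cell sizes
proportionally instead; on the duct+screen fixture the successive
pressure-jump differences shrink monotonically under halving. Full
isotropic refinement of the aneurysm fixture converges only first-order
(stair-step walls), which is why the sac metrics are reported at fixed
fixture resolution rather than extrapolated.

## Numerical choices and degenerate inputs

* Nearest-centroid cell-to-grid mapping; KD-tree lookups are deterministic.
* Braid angle clipped to `(0.05π, 0.95π)`; degenerate cells (area
  < 1e-12 m²) are skipped; `ε = 0` cells are rejected as solid.
* Zero inlet flow returns the exact null field; zero sac inflow leaves the
  turnover time NaN (undefined) rather than raising mid-pipeline.
* Aneurysm attachment requires one dome radius of clearance from the
  vessel ends; the neck disk is recorded for inflow integration, and
  inflow counts only the inward-directed normal component so turnover is
  well defined.
* All runs are bit-reproducible from (config, seed): no randomness is used
  anywhere in the pipeline; the seed is recorded in the run manifest for
  provenance.

## Known limitations

Steady flow only (no pulsatility); rigid walls; planar/axisymmetric
desk-scale domains rather than 3D patient vasculature; stair-step walls
(first-order geometry error); the coil model is a packed-bed stand-in; the
non-Newtonian law is pluggable but defaults to constant viscosity; no
thrombosis or occlusion biology.
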