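# Methods

This note documents the models implemented in `rhizosim`, the numerical
choices behind them, the defaults and their rationale, and what the
synthetic scenarios used in the test suite do and do not emulate.

## State-variable engine

Every quantity in a simulation is a named *state variable* with a unit,
arranged in a tree that mirrors the input document; the hierarchy provides
context (a `branchSpacing` under `rootClasses/taproot` belongs to that
class). Five kinds exist: constants, piecewise-linear time tables,
stochastic draws (drawn once at instantiation from a seeded generator — a
root's vigor must not change between evaluations), derived variables
computed on demand by a registered rate function, and integrated variables
advanced as ODE states.

References between variables are paths: absolute from the tree root, or
relative, searched from the origin upward through its ancestors with the
nearest enclosing scope winning. Sibling names are unique, so resolution is
deterministic; an unresolved path is a fatal configuration error naming the
origin and path.

Integrated variables keep a timetable of `(t, value)` records; any
historical value interpolates linearly, and a query within 1e-9 d of a
recorded point returns the record exactly so histories are immune to float
drift in accumulated step times. All integrated variables advance together
as one coupled system, synchronised at a global maximum step (default
0.1 d). The default scheme is classic Runge–Kutta 4; during sub-stages,
rate functions see stage values of the coupled variables, and queries past
the recorded history return a linear extrapolation (the predictor). A step
is accepted when the corrected end-of-step values agree with that
extrapolation to a relative tolerance (default 1e-3; the adaptive control
halves the sub-step down to a floor of 1e-4 d on disagreement). The
tolerance and floor are design choices: they trade work against the risk of
an interdependent pair of variables drifting between synchronisation
points. Fixed-step behaviour, used whenever the integrator's order is being
measured, is obtained by setting the tolerance to infinity.

Dynamic components (branch roots, tiller plants) are created by generators
attached to a parent variable: when the parent's children are requested the
generator counts how many instances are due (for branch roots,
`floor(length/spacing)`) and instantiates the missing ones by deep-copying
a template subtree. Copies never alias template state, and repeated
requests at the same time are idempotent.

## Root architecture

Coordinates are cm, z up, soil surface at z = 0. A root axis is an ordered
list of stationary vertices plus (while growing) a tip vertex with dynamic
coordinates. Per step, a tip elongates by the exact integral of its
age-dependent rate table (trapezoid on the table's breakpoints, hence exact
for piecewise-linear rates) times vigor times the composed growth
multiplier (carbon × nutrient stress × plasticity, all multiplicative since
each is defined as an independent scaling). The direction then updates by
the tropism sum; with zero weights the direction is untouched, and a
vertically started, gravitropism-only root stays on its axis to machine
precision because no random draw occurs when the impedance weight is zero.

A stationary vertex is dropped each time a full segment length of growth
has accumulated; the segment records the accumulated *grown* length, which
bounds the chord from above, so total root length is conserved exactly
under any discretisation. Segment volume is a truncated cone; secondary
(cambial) thickening raises both end diameters at twice the radial rate,
scaled by a distance-along-root profile and the carbon multiplier.

Branching: positions every `branch_spacing` cm of grown length (an interval
in days converts through the parent's current elongation rate when spacing
is absent), starting one spacing beyond the basal non-branching zone and
excluding the apical zone (both default 0 cm). Branch k of a parent takes
radial angle φ0 + k·360°/n_poles with φ0 uniform per parent on one pole
sector, and the class's axial angle from the parent direction at the
attachment point. A branch's birth time is the parent tip's passage time at
its position plus a per-class emergence delay (2 d in the plant fixtures,
0 by default for architecture-only runs). Roots born within a step begin
elongating at the following step; their recorded birth time is exact, so
age-dependent rates are off by at most one global step at the start of each
root's life. Whorls place n equally spaced adventitious roots on the stem at
a start time; with the shoot-size rule, n scales with the actual-to-potential
leaf-area ratio, floor-rounded (the dependence is biological, the functional
form a design choice). Tillers fire on a time-dependent delay table and are
built as additional axes of the same shared-pool plant.

Anatomy acts through scalar modifiers per segment: living volume fraction
1 − RCA − RCS (applied to respiration and nutrient content), an uptake-area
multiplier 1 + hair lateral area per unit root surface, and a radial
conductivity multiplier equal to the living fraction whenever cortex has
been converted.

Determinism: a single seeded PCG64 stream drives vigor draws, pole offsets
and impedance vectors, consumed in creation order, so a fixed seed
reproduces the architecture vertex for vertex. Multiplier-only features
(plasticity norms, carbon caps) never consume randomness, which is what
makes an identity reaction norm bitwise-identical to a non-plastic run.

## Shoot and carbon economy

The shoot is non-geometric: leaf area, leaf and stem dry weight. Fixation
is RUE × intercepted light with Beer's law (k_ext default 0.65 — a typical
crop canopy extinction coefficient; the interception-from-LAI link itself
is the modelling commitment, the coefficient an input) over a homogeneous
canopy of identical plants. Carbon fraction of dry weight defaults to
0.40 g C g⁻¹; dry weight per carbon is its inverse. The seed reserve
releases linearly over the first 7 days.

Per step: income (fixation + seed release) pays maintenance first
(respiration on living segment volume, exudation per root length, nitrate
uptake cost), then growth sinks are computed — shoot demand from the
potential leaf-area track capped by the allometric ratio, root elongation
demand per sink group from the same elongation integrals the growth step
will use, secondary-growth demand from the potential diameter increment —
and the allocation rule splits what is available. Surplus fills the labile
pool; deficit drains it to zero before the rule cuts sinks (priority
waterfall or uniform proportional). Because elongation is linear in its
multiplier, the carbon actually spent on elongation equals the allocation
exactly; secondary growth is charged at its realised (slightly nonlinear)
volume increase and any unspent allocation returns to the pool. The
resulting per-step ledger — fixed + seed = growth + costs + Δlabile —
closes to float roundoff and is asserted to 1e-6 relative in the tests.

The allometric cap min(1 + recovery, actual/potential leaf area) scales
canopy growth and slows branch formation by widening the effective
branch spacing (a deterministic choice; stochastic thinning would break
seeded reproducibility). With recovery 0 a stressed plant never rejoins its
potential track. Ordering within a step is cap-then-allocate.

## Hydrology

Soil hydraulics use the van Genuchten retention curve with Mualem
conductivity (m = 1 − 1/n). The Richards equation is solved in mixed form
with modified Picard iteration on a regular hexahedral finite-volume
lattice — equivalent to linear FEM on such grids and considerably simpler;
face conductivities are arithmetic means, gravity enters through the total
head h + z, and side/bottom boundaries are closed so a domain with zero top
flux conserves water exactly. Convergence is max|Δh| < 1e-8 cm within at
most 60 iterations; a non-convergent step halves recursively. A hydrostatic
profile is a fixed point of the discrete operator, preserved to better than
1e-8 cm over 10 days in the tests.

The xylem is a linear hydraulic network on the root graph: one node per
vertex, axial conductance Kx/length per segment, each segment's radial
conductance Lp × lateral surface (anatomy-adjusted) acting at its distal
node, branch bases tied to the nearest parent node and parentless axes to
the collar. The sparse Kirchhoff system is solved with a direct solver;
radial flow may reverse (hydraulic lift). The collar carries either a flux
(potential transpiration) or a potential; when the flux solution would pull
any xylem potential below a permitted minimum (default −15000 cm, a
conventional wilting point the model treats as a hard floor) the solve
switches to potential control.

Evapotranspiration is the Penman–Monteith combination equation with the
standard short-surface formulations (saturation-slope, psychrometric
constant, ra = 208/u2); potential transpiration covers the canopy fraction
1 − e^(−k·LAI) and soil evaporation the rest, with bare-soil surface
resistance taken as twice the canopy's and the realised evaporation limited
by the top layer's conductivity. The coupled water step operator-splits
(ET potentials → xylem solve → Richards with radial sinks) at sub-steps of
at most 0.05 d regardless of the global step; surface resistance is a
constant input, not stress-dependent.

## Nutrients

Nutrients are simulated independently; only the stress aggregation step
combines them. The plant-side ledger per nutrient is content (seed reserve
+ cumulative uptake + fixation credit) against requirements obtained by
integrating optimal/minimal concentration tables over organ dry weights
(root contributions scaled by the anatomy content multiplier);
satisfaction = min(1, content/optimal requirement). N fixation credits a
fraction of the optimal requirement without touching soil uptake, and the
nitrate-uptake carbon cost applies to soil uptake only.

Immobile nutrients run a radial depletion model per root segment: finite
volumes on log-spaced radii between the root surface r0 and an outer
zero-flux radius rx = (π·RLD)^(−1/2) (the standard inter-root convention,
clamped to 0.2–2 cm), buffered diffusion plus the inward convective drag of
root water uptake, Crank–Nicolson in time. The boundary uptake uses a
flux-consistent surface concentration — a few Newton steps on "transport
through the inner half-cell = Michaelis–Menten uptake" — and enters the
linear system as a linearised implicit term α·C₀ⁿ⁺¹ with α the chord of
the uptake curve at the current surface state. This is unconditionally
stable and keeps the discrete mass balance exact, because the identical
term is simultaneously removed from the inner cell and credited as uptake;
a 20-node profile reproduces a 200-node reference to ~0.1 % cumulative
uptake over 10 days. Effective diffusion is D0·θ·τ/b with tortuosity
τ = θ^(7/3)/θs² (a Millington–Quirk-type default, configurable). New
segments initialise their profile at the local bulk concentration;
exudation can transfer mass from an insoluble pool into the profile
solution, conserving the total.

Mobile nutrients use an explicit upwind finite-volume
convection–dispersion–diffusion solver on the soil grid, advected by the
Richards face fluxes, with water-content-dependent effective diffusion plus
dispersivity·|q|, Courant-limited sub-cycling, and per-cell uptake sinks
clipped to available mass. Mineralization follows an aging substrate pool
whose relative decomposition rate k(t) = k1·t^(−S) is integrated exactly
over each step (the rate is singular at t = 0, so stepwise evaluation would
depend on the step size); net mineral N follows from the substrate and
microbial C:N ratios and the assimilation efficiency, may be negative
(immobilization), and ignores soil moisture and temperature.

Stress curves default to multiplier = satisfaction clamped to [0, 1], with
per-process response curves overridable; aggregation over nutrients is
maximum-stress (minimum multiplier) or mean. All organs experience equal
stress.

## Plasticity

Scattered environmental fields interpolate by inverse-distance weighting
(power 2, 8 nearest neighbours — defaults chosen for smoothness and
exactness at data points); grid-backed fields interpolate trilinearly. A
reaction norm is a piecewise-linear curve from the locally sensed scalar to
a multiplier, clamped outside its domain, optionally scaled by a second
norm on a whole-plant variable. Norms target branch spacing (spacing is
divided by the multiplier, so >1 means denser branching — spacing scaling
rather than per-branch probability keeps runs deterministic), elongation,
or gravitropism strength. Sensing happens at tip positions for
elongation/gravitropism and at prospective branch positions for branching;
only absolute scalar values are sensed, never gradients.

## Geometry

All descriptors clip segment chords (against depth bins, vertical
cylinders, or depth planes) and scale the clipped chord by the segment's
grown/chord ratio, so totals are true lengths and the depth profile sums
to the total exactly. D90 interpolates linearly within the crossing bin.
The depletion-zone overlap metric is a deliberately coarse pairwise count
of segment midpoints within 2·rx of each other, intended as a relative
indicator only.

## Input and output

Parameter documents are XML in a six-element dialect (`SimulaConstant`,
`SimulaTable`, `SimulaStochastic`, `SimulaDerivative`, `SimulaVariable`,
plus the grouping `SimulaBase`); unrecognised elements are fatal rather
than ignored, unknown function names fail at parse time listing the
registry, and a physical constant without a unit warns. The canonical dump
(fixed attribute order, shortest round-trip float formatting) is a byte
fixed point under parse∘dump. Root systems export as legacy ASCII VTK
polydata (one polyline per root; per-point age and diameter, per-cell class
id), written and verified by a deliberately separate minimal reader.
Measured architectures import as per-root polylines with topology; missing
node times are estimated from topology — a lateral's base time is the
parent's passage time at the attachment plus an emergence delay (2 d
default), and within-root times interpolate linearly in arc length up to
the observation time.

## The synthetic scenarios

The fixture generator emits five self-contained scenarios used throughout
the tests: `minimal` (the two-variable relative-growth model whose analytic
solution is e^{0.1t}), `dicot_like` (taproot + basal whorl + laterals, with
secondary growth and a P budget), `monocot_like` (primary + nodal whorls +
tillers), `plasticity_demo` (a static P field rich in the top 12 cm with a
branching reaction norm) and `hydro_demo` (an 8×8×10 soil grid, constant
weather, nitrate). Parameter values are in the range of published crop
parameterisations: P uptake kinetics Imax 0.26 µmol cm⁻² d⁻¹, Km
0.003 µmol cm⁻³; nitrate Imax 5, Km 0.05; seed reserves 0.08 g C, 25 µmol
P, 270 µmol N (roughly a large-seeded annual); optimal tissue
concentrations 100 µmol P and 1500 µmol N per g dry weight.

`plasticity_demo` is deliberately *source-limited* — low light
(4 MJ m⁻² d⁻¹), a small seed reserve and vigorous laterals — because the
trade-off it demonstrates (denser branching where P is rich, at the cost of
individual lateral length where it is poor) only exists when branch roots
compete for a fixed carbon supply; under ample carbon, extra branches are
free and the contrast vanishes.

What the scenarios do not emulate: field weather variability (drivers are
constant), soil heterogeneity beyond layered profiles, inter-plant
competition (one plant per domain, periodic in x–y), root decay and
turnover, and drought feedback on growth (soil drying reduces water and
nutrient delivery but not elongation directly). Passing tests therefore
demonstrate internal consistency — conservation, convergence, analytic
limits, reproducibility and the qualitative response patterns built into
the model — not predictive accuracy for any particular crop or field.

## Problem sizes

The test suite and the acceptance script run desk-scale configurations
chosen as the smallest sizes at which each property is meaningful: 10-day
plants with tens of roots, an 8×8×10 soil grid at 5 cm spacing, 20-node
radial profiles (200-node self-oracles), and 20 seeded replicate pairs for
the plasticity contrast. The whole verification pass completes in well
under a minute on one CPU.

## Known limitations

- The whole-plant driver advances by operator splitting at the global step
  rather than routing every plant variable through the RK4 tree; coupling
  errors are first-order in the global step (0.1 d default).
- Roots created mid-step begin growing at the next step.
- The priority allocation can starve root growth entirely in the first
  hours of a seedling's life while shoot demand exceeds seed-release income;
  this is the rule's intended behaviour, not a solver artefact.
- Segment-to-soil-cell mapping assigns each segment's sink to the cell
  containing its midpoint (no length-weighted splitting across cells).
- The solute solver is explicit and first-order upwind; fronts smear by
  numerical dispersion of order v·Δx/2.
- Nutrient tropism is off by default; only a placeholder vector interface
  exists.
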