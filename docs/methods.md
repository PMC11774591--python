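# Methods

## Model

The package treats a rigid, homogeneous, avascular cell construct (M-CELS)
as a porous disc in a straight microfluidic channel with reservoirs at both
ends held at the inlet concentration.  Three nested supply regimes are
solved:

* **Maximal supply** — the fluid–construct interface is pinned at the
  source concentration (interface concentration γ* = 1).  This is the
  theoretical optimum of any culture device and depends only on the
  Damköhler number and the construct shape.
* **Static** — no flow; solute diffuses from the reservoirs through the
  channel to the interface.  Supply is measured by the diffusive supply
  number `Sd = 2*Rd/Da`.
* **Microfluidic** — a steady channel flow convects solute to the
  interface; supply is measured by `Sc = Sd*Pe1`.

Consumption follows Michaelis–Menten kinetics `R = Rmax*c/(c + K_half)`.
The quasi-1D analytical layer replaces it by a sharp cutoff (constant
consumption wherever solute is present, a necrotic radius where the
concentration reaches zero with zero gradient), which is accurate when
`K_half* = K_half/c0 << 1`.

Assumptions inherited from that construction: steady state; rigid,
homogeneous construct (early-stage, undifferentiated tissue); solute does
not decay in the channel; transpiration through the construct is negligible
for transport (`Pe2 = k*v0/(a*D2) < 0.1`, enforced with a warning); 2D
plane geometry (the cylinder analogue — sphere constants are provided in
the analytical layer only: onset 6, supply factors `3*Rd/Da`).

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| `K_half_star` | `1e-4` | an order of magnitude below the necrosis threshold `cn* = 1e-3`, so the Michaelis–Menten concentration floor (which scales with K) cannot register as survival at the threshold.  With `K* >= cn*` the measured necrosis onset drifts ~25% above its sharp-kinetics value and the live fraction acquires a spurious `sqrt(K/Da)*ln(K/cn)` rim shift. |
| `cn_star` | `1e-3` | generic survival threshold as a fraction of the source concentration. |
| `k_star` | `1e-8` | nondimensional Darcy permeability `k/a^2`; tissues have `k <= 1e-14 m^2` and radii `>= 100 um`, so the construct is quasi-solid to the flow while still admitting transpiration. |
| `q` | `1e-3` | peak speed of the largest corner-recirculation eddy over the inlet peak velocity (geometric Moffatt decay in a sub-40° wedge); configurable, used only in the corner supply numbers. |
| `Re` | `0.1` | creeping-to-transitional chamber flow; the solver handles up to ~10 by Picard iteration. |
| chamber | `L = 10a`, height `3a` (unconfined), apex clearance `0.4a` (confined) | generic chamber proportions that keep a visible constriction between the construct and the ceiling.  All constants extracted from chamber sweeps (prevention factors, approach products) are properties of *these* proportions; see Limitations. |

The confined construct is a disc truncated so its height above the floor is
90% of its diameter: circle centre `0.8a` above the wall, contact chord
half-width `0.6a`, fluid wedge angle ≈ 36.9° at each contact point.

## Numerics

**Meshing.**  Unstructured Delaunay meshes built in-package: boundary and
interface curves are discretized with graded spacing (geometric bands with
ratio 1/2 over four levels toward the contact corners; spacing capped at a
fifth of the apex–ceiling gap so the constriction is always resolved);
interior points come from a jittered multi-level grid filtered by the
sizing field, relaxed by a distmesh-style truss iteration plus centroidal
polishing.  Interface segments keep their diametral circles point-free (the
Gabriel condition), which makes them Delaunay edges by necessity — region
conformity is guaranteed, not hoped for.  Minimum interior angles exceed
20° at every packaged resolution.  Meshing is deterministic given a seed;
re-seeding moves the live fraction by < 0.3% at default resolution.

**Flow.**  Single-domain Navier–Stokes–Brinkman: the construct contributes
a resistive `(1/k*) v` term, so pressure and velocity continuity at the
interface hold naturally and the interior Darcy limit is recovered.
Equal-order P1–P1 velocity–pressure with PSPG-type stabilization whose
parameter degenerates to `k*` inside the construct (the standard stabilized
equal-order Darcy limit); convection linearized by Picard.  Global mass
conservation holds to solver precision (the constant is in the pressure
test space); the inlet profile is the parabola with unit peak.

**Transport.**  P1 Galerkin with the Michaelis–Menten sink integrated by
nodal (lumped) quadrature — together with the Delaunay Laplacian this keeps
the single-region operator an M-matrix, so maximal-supply and
construct-only solves honour the discrete maximum principle to 1e-8.
Channel advection uses streamline (SUPG) stabilization with the optimal-τ
rule; stabilization is off inside the construct (diffusion–reaction only).
Newton with backtracking, plus a continuation ladder in the half-rate
constant (solve soft, sharpen stepwise) that converges every packaged case
up to Da = 100.  The nonlinearity is evaluated at `max(c, 0)` so Newton
stays defined on undershooting iterates; converged fields are verified
non-negative.

**Observables.**  The necrotic boundary, area and barycentre are computed
exactly per element from the P1 interpolant (polygon clipping of each
triangle by the threshold plane) — no contouring grid.  The barycentre is
mass-normalized by default (first moments over the necrotic area), with the
whole-construct normalization available.  "Fully supplied" is decided by
`min c >= cn` so onset searches carry no contouring noise.  Threshold
constants are extracted from sweep tables by log–log interpolation of the
crossing (the concentration minimum decays exponentially through the
threshold, so log-ordinate interpolation is the faithful scale; this was
validated against dense scans of the crossing).

**Radial oracle.**  An independent 1D check for the FEM: the radially
symmetric Michaelis–Menten problem solved by a conservative finite-volume
discretization on a grid strongly refined across the cutoff layer
(width `sqrt(K/Da)`), with its own Newton/continuation.  The 2D field
matches it to < 1% relative L2 at default resolution.

## Problem sizes

Default meshes: ≈ 330 nodes (unconfined construct), ≈ 640 (confined
construct), ≈ 1050/1620 (full unconfined/confined chamber); "fine" halves
the characteristic sizes.  Packaged studies use reduced grids — Da in
{1,2,3} with Rd at 3 points/decade over [0.1, 100] for the static
prevention constant; Da in {2,3} with 8 log-spaced Sc for the microfluidic
one; Da in {5,10} for the approach and confinement-excess studies; 14
log-spaced Pe1 for the asymmetry sweep.  The full acceptance run takes
about a minute on one CPU.

## Design choices where the design was open

* The velocity-threshold constant in the prevention condition written as an
  inlet velocity is exposed as a convention flag (`constant_divide`,
  default: divide by 4), since the two readings differ by a factor 16 and
  only the proportionality `vdif2*(1/Da - 1/4)` is structural.
* The corner Péclet number is implemented in the closed form
  `q*Pe1*(sqrt(1 + Rd*Sd) - 1)/2`, derived from the no-flow interface
  gradient with the static boundary-layer thickness; its deficient-supply
  scaling `q*Rd*Sc` is exposed separately and the exact small-`Rd*Sd`
  prefactor between the two (1/4) is pinned by a test.
* Sphere variants of the necrotic-radius equations are derived from the
  same zeroth-order construction in spherical coordinates; their anchor is
  the onset value 6.
* The unconfined chamber is solved on the upper half-domain with a symmetry
  line through the disc centre; construct-only quantities are
  symmetry-unfolded where a physical (full-disc) measure is reported.

## Limitations

* Constants extracted from chamber sweeps (the microfluidic prevention
  factor, the supply-approach product `Rd*Sd*Sc`, the confined static
  excess) depend on the chamber proportions.  With the packaged defaults
  the diffusive screens (interface boundary layer, corner eddies) delay the
  approach to maximal supply by a factor ~3 relative to the quasi-1D
  theory; stronger constrictions or longer chambers raise that delay
  substantially, so these constants should be recomputed for a specific
  device rather than quoted.
* Two-region solves (channel + construct) show a bounded undershoot of
  order 1e-3 localized to the empty necrotic core: the diffusivity jump
  across interface edges (up to `D1/D2 ~ 1e3`) breaks the exact M-matrix
  property.  Affected nodes are deeply necrotic regardless, so threshold
  classifications are unchanged; single-region solves are monotone to 1e-8.
* SUPG-stabilized advective solves can overshoot the source concentration
  by < 1e-3 near sharp layers at `Pe1 >~ 1e3`.
* The synthetic chambers emulate layout, confinement and supply topology —
  not any specific commercial device; no transient growth, cell
  differentiation, vascularization, shear-stress biology, or 3D (spherical
  constructs enter only through the 1D analytical layer).  Passing tests
  demonstrate internal consistency and agreement with the quasi-1D theory
  under these idealizations, not predictions for a particular real chip.
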