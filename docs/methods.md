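# Methods

## Model

The simulation volume is a cube of side 64 µm discretized into a 128³
voxel grid (0.5 µm voxels; both configurable).  Vessels are unions of
capped cylinders of one radius built from *fork* centerlines:

* the trunk runs from the x = 0 face to the cube center along +x, length
  *a* = 32 µm (half the cube side);
* two branches leave the center at ±β from the trunk axis inside the
  xy-plane (so the inter-branch angle is 2β) with length
  *a*/max(cos β, sin β), terminating on a cube face.  This is the unique
  convention reproducing the closed-form total lengths 2*a*, *a*(1+2√2)
  and 3*a* at β = 0°, 45°, 90° and the "T" shape at 90°;
* the rotation angle φ turns the whole arrangement rigidly about the
  fork-plane normal (+z) through the cube center.

β = 0 is degenerate: both branches coincide with the trunk's continuation
and the centerline is a single face-to-face chord, counted once in the
length.

**Orientations.**  The geometry stays fixed and B₀ rotates: orientation 1
is B₀ = ẑ (normal to the fork plane, trunk at θ = 90°), orientation 2 is
B₀ = x̂ (along the unrotated trunk, θ = 0°), orientation 3 is B₀ = ŷ
(in-plane, perpendicular to the trunk, θ = 90°).  Under this convention
orientations 2 and 3 are exact mirror images of each other through
φ → 90° − φ (the grid reflection x ↔ y maps one onto the other), which the
tests verify on simulated rates.

**Multi-fork packing.**  1–9 forks share the cube with parallel trunks and
parallel fork planes.  Straight segments (β = 0) sit on the classical 3×3
lattice in the (y, z) cross-sectional plane (spacing 64/3 µm; center
first, then corners, then edge midpoints).  Bifurcated forks are stacked
center-out along the fork-plane normal with spacing 64/*n* µm.  The
in-plane lattice cannot be used for β > 0: two forks in the *same* fork
plane offset along y have branches that provably cross for most
bifurcation angles (at β = 90° the branches are collinear), whereas
plane-normal stacking keeps every pairwise clearance equal to the z-offset
regardless of β and φ.  Packing feasibility is never assumed: after
rasterization the per-fork masks are checked pairwise and any shared voxel
raises `OverlapError`.  A genuine limit follows from the geometry: nine
d = 8.6 µm forks with β > 0 cannot be packed overlap-free under parallel
fork planes at all (nine branch lines would need pairwise separation
≥ 8.6 µm, i.e. ≥ 77 µm of z-extent in a 64 µm cube), so sweep drivers log
such cells as missing rather than fabricating a layout.

**Rasterization.**  A voxel is intravascular iff its center lies within
one radius of any centerline segment (binary assignment, no
partial-volume weighting); voxels covered by several segments count once.
Rasterization is clipped to the cube: geometry carried past a face by the
in-plane rotation is cut, not wrapped — the voxel matrix holds what the
cube contains, and the FFT field solver then periodizes the cube as a
whole.  For face-to-face segments (φ = 0° or 90°) clipping and periodic
wrapping give identical masks, so a β = 0 chord behaves as an infinite
cylinder under the periodic boundary.  Interior voxels carry χ_SI = 4π·χ
(cgs values at the interface, SI internally); the volume fraction *f* is
the intravascular voxel count over 128³.

## Field solver

ΔB = B₀ · FT⁻¹[(1/3 − (k·b̂)²/|k|²) · FT[χ_SI]] on the voxel grid, the
standard k-space dipole kernel for the field component along B₀.  Choices:

* the k = 0 coefficient is set to zero, i.e. the field is referenced to
  its volume mean.  A global offset adds a common phase to every proton
  and cannot change any signal magnitude;
* no Lorentz-sphere correction: only extravascular protons are simulated
  and only field *differences* matter at fixed TE;
* B₀ defaults to 1.0 T (configurable).  At χ = 3×10⁻⁸ cgs this makes the
  equatorial frequency offset Δω = γ·2πχ·B₀ ≈ 50 rad/s, matching the
  ~51 rad/s transition frequency of the smallest vessel at D = 10⁻¹⁰ m²/s;
* the FFT makes the cube periodic; this is the boundary model throughout
  (walkers wrap consistently).

The closed-form exterior field of an infinite cylinder,
ΔB = B₀·2πΔχ·(R/r)²·cos 2φ·sin²θ, is implemented independently as the
oracle.  The FFT solution agrees with it to ≤ 5% for 1.5R ≤ r ≤ 3R once
the one free constant between the two zero references (volume mean vs
infinity) is fixed; the residual is rasterization error plus the periodic
image lattice.

## Random walk and echoes

* N walkers start uniformly in the continuous extravascular volume
  (rejection sampling against the voxel mask; bounded rounds, failing
  loudly if the extravascular space is essentially empty).
* Per step, each coordinate moves by an independent zero-mean Gaussian
  with σ = √(2DΔt), Δt = 0.1 ms; positions wrap modulo the cube side.
* Impermeability is enforced by full-step rejection: a step whose endpoint
  voxel is intravascular is discarded and the walker waits one step.
  Rejection is the simplest rule that preserves the extravascular
  invariant exactly; elastic reflection is the documented alternative and
  would slightly alter the near-wall residence statistics.
* Phase accrues as γ·ΔB·Δt from the voxel containing the walker after the
  move (nearest-voxel lookup, matching the binary susceptibility grid).
* One 90°–180° pair: 50 steps to the 180° pulse at τ_CP = 5 ms, 50 more to
  the echo at TE = 2τ_CP = 10 ms.  Both signals come from the same
  trajectories: s_ge = |⟨e^{iφ(TE)}⟩| and s_se = |⟨e^{i(φ(TE) − 2φ(τ_CP))}⟩|
  (the 180° pulse negates accumulated phase).  The gradient echo is read
  at the same TE so the two rates are directly comparable.  At D = 0 the
  spin echo refocuses exactly (s_se = 1 to machine precision), a property
  the tests assert.
* One PCG64 stream per simulation, seeded explicitly; identical
  (seed, parameters) give bit-identical results.  Sweep cells derive their
  seeds from the master seed and a hash of the cell parameters, so any
  subset of a sweep reproduces in isolation and interrupted runs resume
  identically.

## Rate estimation

R2\* and R2 are obtained by ordinary least squares of ln S(TE) on the
volume fraction across segment counts {1, 3, 5, 7, 9} (five distinct *f*
values), with `rate_per_f = −slope/TE` in s⁻¹ — the "per volume-fraction
unit" normalization that removes vessel-length dependence.  Natural
logarithms; the intercept is estimated rather than pinned at 0 so small
non-exponential transients do not bias the slope.  Non-positive signals
(total dephasing) abort the fit with a diagnostic naming the offending
record.  The fit's r² is reported alongside; simulated series at the
default scales fit with r² ≈ 0.99.

Regime classification is label-only and never alters computation: the
gradient echo is MAR iff Δω·τ_D < 1 (strict; the boundary classifies as
SDR) and SDR otherwise; the spin echo is additionally ELR when
τ_D > 2τ_CP.  The echo-limited expression's printed denominator 4R² is
dimensionally ambiguous; it is resolved as R² = τ_D·D, i.e. a 4τ_D
denominator, keeping the rate in s⁻¹ for any unit choice.  The numeric
prefactor 7.2/4 is implemented as printed.

## Sweeps, τ_D summaries and ANOVA

`run_sweep` crosses the factor lists (angles × orientation × diameter ×
diffusion × susceptibility), reusing geometry masks across the inner loops
and unit-susceptibility fields across χ (the field is linear in χ).
Per-cell failures (packing overlap, total dephasing) are logged and left
missing, never fatal.  Results accumulate in a resumable CSV keyed by a
parameter hash.

The correlation-time summary groups rates by τ_D = R²/D and averages
across the angle cells, reporting the SEM (zero by convention for a single
cell).  The τ_D ladder is realized as (radius, diffusion) *pairs*,
R = √(τ_D·D), choosing the fastest of the three study diffusion rates that
keeps the radius inside the capillary range 1.4–4.3 µm: covering
τ_D ∈ [2, 100] ms at a single D would require radii up to 10 µm, which
neither fit the capillary range nor pack without overlap.

Angle effects are tested with a two-way ANOVA **without replication** —
the sweep tables carry exactly one rate per (β, φ) pair, so the
interaction is the error term.  Degenerate inputs follow fixed
conventions: a constant response gives F = 0, p = 1; a zero residual with
a nonzero factor effect gives F = ∞, p = 0.  The decomposition is verified
against a brute-force mean-model computation and against an independent
OLS/ANOVA route, and the null type-I rate is checked at 0.05 over 500
replicates.  No multiple-testing correction is applied (per-table tests at
a flat 0.05 threshold).

## What the simulations do and do not emulate

The geometry generator reproduces idealized study conditions: straight
rigid segments of a single radius, binary susceptibility, no flow, no wall
permeability, no intrinsic T1/T2, no intravascular signal, a single echo
rather than a CPMG train.  Real microvasculature is tortuous, polydisperse
and perfused; passing tests therefore demonstrate correctness of the model
*as specified*, not fidelity to in-vivo tissue.  Curved centerlines,
trifurcations and multi-cube networks are out of scope.

Two physical findings from the validation runs are worth stating because
they bound what the analytic formulas can promise at this sequence timing:

* at the fast-diffusion cell (d = 2.8 µm, D = 10⁻⁹ m²/s) the spin-echo
  rate is ≈ 0.5× the gradient-echo rate rather than equal: τ_D ≈ 2 ms is
  a sizeable fraction of τ_CP = 5 ms, so the 180° pulse refocuses part of
  the "motionally averaged" dephasing.  An independent continuum oracle
  (walk around one cylinder using the closed-form field, no grid, no FFT)
  reproduces the same ratio, so this is physics of the TE = 10 ms single
  echo, not a discretization artifact.  The asymptotic MAR equality
  requires τ_D ≪ τ_CP.
* the mean spin-echo rate on the reduced τ_D ladder at χ = 10⁻⁷ cgs peaks
  at τ_D = 5 ms, one log-rung below the 2τ_CP = 10 ms echo-limited onset,
  because at this susceptibility Δω·τ_D reaches 1 (at τ_D ≈ 6 ms) before
  the echo condition does.  The peak location depends on the χ·B₀ product;
  at the lowest study susceptibility the echo condition governs and the
  peak moves to ≈ 10 ms.

The static-dephasing plateau (2π/√27)·Δω·f is an orientation average
(⟨sin²θ⟩ = 2/3); a purely perpendicular cylinder sits a factor 3/2 above
it.  Tests compare the plateau against the mean over the three canonical
orientations, whose ⟨sin²θ⟩ is exactly 2/3.

## Problem sizes

Defaults target a single desktop CPU: 128³ grids throughout, 10 000
walkers for single-cell rate estimates, 4 000 for the τ_D ladder scan
(2 000 in the test suite), and reduced angle sets {0°, 45°, 90°} where a
full 7×7 angle grid is not needed.  Monte Carlo precision of a fitted rate
scales as √(2/N) ≈ 1–3% at these sizes.  The full production grids
(7×7 angles × 3 orientations × 3 diameters × 3 diffusion rates × 3
susceptibilities at 40 000 walkers) are expressible with the same
`SweepGrid` defaults and are resumable, but are meant for long unattended
runs.
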