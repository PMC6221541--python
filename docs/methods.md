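# Methods

## Model

The package integrates a two-species activator–inhibitor system with
clamped-linear kinetics (a Kondo–Miura-style model):

    ∂u/∂t = F(u, v) − d_u u + D_u ∇²u
    ∂v/∂t = G(u, v) − d_v v + D_v ∇²v

where F and G are linear in (u, v) but truncated to [0, F_max] and
[0, G_max]. The clamps are exact piecewise rules (no smoothing, no epsilon
at the breakpoints): production can neither be negative nor exceed a
saturation rate. Within the clamps the model is linear, which makes the
homogeneous steady state and its stability fully analytic; the clamps are
what arrest the linear instability into a finite-amplitude spot pattern.

Assumptions worth keeping in mind: concentrations are continuous fields (no
cell discreteness), kinetics are deterministic, the domain is a fixed,
flat square (no growth, no curvature), and the initiator row is imposed as
an initial condition rather than produced by an upstream mechanism.

## Parameters

The baseline ("catshark") constants, in model units (time and length are
non-dimensional; diffusivity is area per unit time):

| symbol | value | meaning |
|---|---|---|
| a_u | 0.08 | activator self-production |
| b_u | −0.08 | inhibition of activator by inhibitor |
| c_u | 0.04 | activator constitutive production |
| F_max | 0.2 | activator production ceiling |
| d_u | 0.03 | activator degradation rate |
| D_u | 0.02 | activator diffusivity |
| a_v | 0.16 | activation of inhibitor by activator |
| b_v | 0 | inhibitor self-term |
| c_v | −0.05 | inhibitor constitutive offset |
| G_max | 0.5 | inhibitor production ceiling |
| d_v | 0.08 | inhibitor degradation rate |
| D_v | 0.6 | inhibitor diffusivity |

Domain L = 75, end time T = 1500, grid n = 128 (dx = L/128 ≈ 0.586), seed
concentration u₀ = 5. The initiator rows: six spots of radius 4.5 at
(iL/5, L/2) for the catshark (the outermost two centers sit on the domain
boundary and are seeded as clipped half-discs), the same row minus the
third spot for the gap experiment, and three spots of radius 5.25 at
((3i+2)L/10, L/2) for the skate regimes.

The two sparser regimes move only in the directions that slow and spread
the inhibitor and starve the activator: `thornback` sets d_v = 0.06,
G_max = 0.3, D_v = 1.0; `little_skate` additionally sets c_u = 0.02. These
four numbers are a calibration, not measured constants — many combinations
within the same directions produce similar patterns. Both retuned parameter
sets remain Turing-unstable (verified analytically by `turing_check`), and
their fastest-growing wavelength rises from 6.7 to 7.4, which together with
the reduced activator supply thins the pattern.

## Numerics

* Grid: n×n cell-centered nodes at ((i+0.5)dx, (j+0.5)dx). No-flux
  boundaries are mirror ghost cells (the outside neighbor takes the
  boundary cell's value), the standard second-order Neumann treatment; the
  discrete Laplacian then sums to zero over the grid, so pure diffusion
  conserves mass exactly.
* Time stepping: forward Euler with dt = dx²/(8·max(D_u, D_v)) — half the
  explicit 2D diffusion limit dx²/(4D). The rule uses the larger
  diffusivity so it stays safe if a user swaps the species' roles, and it
  is re-derived per preset, so raising D_v to 1.0 automatically shrinks dt
  from ≈0.0715 to ≈0.0429.
* The run takes floor(T/dt) whole steps; no partial final step. All
  arithmetic is double precision; runs are bit-reproducible on a platform.
* Blow-up (any non-finite cell) raises an error naming the failing step;
  it cannot occur under the dt rule, only with manual dt overrides.
* Disc rasterization tests cell centers against the strict inequality
  (x−x_i)² + (y−y_i)² < R², ties excluded; the initial-condition builder
  and the synthetic fixture generator share one membership routine.

Steadiness is reported as max over cells of |Δu|/dt (and |Δv|/dt) over the
final step — an L∞ measure of how fast the pattern is still changing.

## Pattern quantification

Spot boundaries are not intrinsic to a concentration field, so the analysis
defines them: binarize at min + 0.5·(max − min) (half-range; the steady
pattern is high-contrast, and sweeping the fraction over 0.3–0.7 leaves the
qualitative verdicts unchanged — see the threshold-sweep test), label
8-connected components, and drop components under 3 cells (numerical
speckle at n = 128). A spot is initiator-flagged iff its footprint contains
the grid cell of a non-removed initiator center — unambiguous, and robust
to modest spot drift, though at very coarse resolution (n = 64) and long
horizons drift can move a center outside its spot. Density is spot count
over L²; spacing regularity is the coefficient of variation of
nearest-neighbor centroid distances (scipy KD-tree); gap infilling counts
emergent spots whose centroid lies within 1.5·R_spot of a removed center
and compares their mean area with the surviving initiator spots'.

## Synthetic fixtures

`synthetic_spot_field` builds idealized disc fields with known geometry so
the analysis stage is tested independently of the solver. These fixtures
emulate only the geometry of a spot pattern — crisp, uniform-intensity,
perfectly circular spots. They do not emulate the graded amplitudes,
irregular shapes, or background structure of a real steady-state field, and
say nothing about biological images; tests passing on them establish the
correctness of the measurement code, not of the biology.

## Behaviour and timescales

With the baseline constants the pattern nucleates off the initiator row
and invades the domain as a front (maximal linear growth rate ≈ 0.0117,
wavelength ≈ 6.7). The invasion completes around t ≈ 1700–2000: at
t = 1500 the spot count is still settling (88 at t = 1500 vs 80 from
t = 2000 on) and max |∂u/∂t| ≈ 7×10⁻³. After the front completes, the
field relaxes through slow drift of spot positions; this near-neutral mode
keeps the L∞ steadiness at a few 10⁻⁴ out to t = 8000 (independent of dt,
so it is dynamics, not time-stepping noise). "Steady state" for this model
therefore means the spot count and layout have stopped changing, not that
the L∞ rate of change is negligible at T = 1500; the pattern metrics are
insensitive to extending T.

## Design choices and limitations

* Linear stability is analyzed on the unclamped expressions and refuses a
  steady state that sits on a clamp (linearization at a kink is
  meaningless). The baseline steady state (0.818, 1.011) sits strictly
  inside both clamps.
* The Turing validator is a consistency check the package adds; the model's
  authorship of patterns is established by the simulation itself.
* Grid-refinement robustness: spot counts shift by a few spots under
  resolution doubling (the wavelength is only ~6 cells at n = 64 and ~11
  at n = 128); the suite requires agreement within 10% at a settled
  horizon rather than exact counts.
* Replicate-proportion summaries round half-up to integer percent
  (20/23 → 87).
* Not modelled: stochastic kinetics, domain growth, mechanochemistry,
  nonlinear (Gierer–Meinhardt/Gray–Scott) production terms, non-square
  domains, and any fitting to biological images.
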