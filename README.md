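# denticle-rd

Reaction–diffusion modelling of shark denticle patterning.

Shark skin denticles (tooth-like skin appendages) erupt in a precise spatial
pattern that begins with a dorsolateral row of enlarged placodes. This
package implements an activator–inhibitor model of that process: a
pre-patterned initiator row of activator spots triggers a Turing-type
instability that propagates a periodic spot pattern across the flank. It is
aimed at researchers studying skin-appendage patterning who want a small,
fully tested simulation-and-quantification pipeline rather than a one-off
script.

## Model

Two morphogen fields, an activator *u*(*t*, *x*, *y*) and an inhibitor
*v*(*t*, *x*, *y*), evolve on the square domain 0 < *x*, *y* < *L* with
no-flux boundaries:

```
∂u/∂t = F(u, v) − d_u u + D_u ∇²u
∂v/∂t = G(u, v) − d_v v + D_v ∇²v
```

with clamped-linear production

```
F(u, v) = clamp(a_u u + b_u v + c_u, 0, F_max)
G(u, v) = clamp(a_v u + b_v v + c_v, 0, G_max)
```

The activator promotes both species (a_u, a_v > 0), the inhibitor suppresses
the activator (b_u < 0), and the inhibitor diffuses much faster than the
activator (D_v ≫ D_u) — the classic substrate for diffusion-driven (Turing)
instability. The initial condition seeds *u* = u₀ on a row of discs
(the initiator row); *v* starts at zero. Integration is explicit finite
differences: a five-point Laplacian with mirror ghost cells and forward
Euler at dt = dx²/(8·max(D_u, D_v)).

Four presets are included: `catshark` (dense baseline), `catshark_gap`
(baseline with one initiator spot ablated — the in-silico analogue of a
local-inhibition bead experiment), and the sparser `thornback` and
`little_skate` regimes (inhibitor degradation and production ceiling
lowered, inhibitor diffusivity raised; the little-skate regime additionally
lowers the activator's constitutive production).

The analysis stage segments spots from the final activator field
(half-range threshold, 8-connected components), splits them into initiator
vs emergent, and reports counts, areas, coverage density, nearest-neighbor
spacing, and gap-infill statistics.

## Worked example

```
$ denticle-rd check --preset catshark
preset catshark
  dx = 0.585938, dt = 0.0715256, steps = 20971
  steady state: u* = 0.818182, v* = 1.01136 (clamps inactive: True)
  Jacobian: [[0.05, -0.08], [0.16, -0.08]]
  trace = -0.03, det = 0.0088
  stable without diffusion: True
  Turing unstable: True
  growing wavenumbers: k^2 in (0.3667, 2)
```

The homogeneous steady state is stable on its own (trace < 0, determinant
> 0) but perturbations with squared wavenumber between 0.37 and 2.0 grow
once diffusion acts — the fingerprint of a Turing instability. The fastest
growing mode has wavelength ≈ 6.7 length units, which sets the spot spacing.

```
$ python analysis/02_catshark_baseline.py
simulated to t = 1499.96 (20971 steps), steadiness 7.01e-03
spots: 88 total, 6 initiator-flagged, 82 emergent
mean area: initiator 14.65 vs emergent 7.10 (ratio 2.06)
nearest-neighbor distance: mean 7.92, CV 0.102
```

All six initiator spots persist and remain about twice the area of the
emergent spots; the nearest-neighbor coefficient of variation of 0.10 marks
a periodic, not random, arrangement.

```
$ python analysis/03_gap_ablation.py
removed initiator center: (30.0, 37.5)
spots within 6.75 of the removed center: 4
mean gap-spot area 6.52 vs surviving initiator mean 14.01 -> infill by smaller spots: True

$ python analysis/04_density_retuning.py
spot counts: {'catshark': 88, 'thornback': 43, 'little_skate': 41}
strictly decreasing: True
```

Ablating one initiator spot leaves a gap that four smaller emergent spots
occupy, and retuning the kinetics toward the skate regimes strictly reduces
coverage density.

The numbered scripts under `analysis/` run each experiment end to end and
write fields, per-spot tables, metrics JSON and heatmaps under `results/`.
The same pipeline is scriptable (`denticle-rd run --preset catshark --out
DIR --set T=500`) and importable (`denticle_rd.run_preset`).

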