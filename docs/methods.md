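# Methods

## The model

`fclsim` simulates the assembly and disassembly of flat clathrin lattices
(FCLs) on a patch of plasma membrane with a particle-based
reaction–diffusion model. The simulation domain is a cube of edge
L = 1 μm; its bottom face (z = 0) is the membrane, the volume above is
cytosol. Two species are modelled:

* **Clathrin** — a rigid planar triskelion with three clathrin-binding leg
  sites at 120° intervals (radius 12.5 nm from the hub in the body x–y
  plane) and one AP-2-binding site 2 nm below the hub along −z. Clathrins
  diffuse in 3D (translation and rotation) and carry a 10 nm excluded
  diameter (minimum hub–hub distance).
* **AP-2** — the adaptor that recruits clathrin to the membrane, a
  zero-volume dot confined to z = 0. Clathrin-free AP-2 is not represented
  explicitly: it forms a well-mixed implicit pool with a surface density
  `free_count / L²`. Only clathrin-bound AP-2 exists as particles, located
  directly beneath the host's AP-2 site.

### Reactions

* **Clathrin–AP-2.** When a clathrin's AP-2 site dips into a capture layer
  of height h = 10 nm above the membrane, it binds an AP-2 from the
  implicit pool with per-step probability `1 − exp(−(k₃D/h)·ρ_free·Δt)`.
  On binding, a free clathrin is reoriented so its AP-2 site axis is
  perpendicular to the membrane (leg plane parallel to z = 0, azimuth
  preserved) and an AP-2 instance is created at z = 0 beneath the site.
* **Clathrin–clathrin.** Head-to-head leg binding. The rate is *gated*:
  zero unless at least one partner belongs to an AP-2-containing cluster
  (evaluated at cluster level, since every assembly nucleates from
  AP-2-bound clathrin). The bound pose is constructed analytically: bound
  sites exactly 5 nm apart (the bond gap), both hubs and all six leg sites
  coplanar. This produces planar hexagonal lattices with a ~30 nm hub
  spacing.
* **Dissociation.** Each bond tests `1 − exp(−koff·Δt)` per step
  (Poisson process); dissociations are tested before associations, and a
  molecule takes part in at most one reaction per step (participants skip
  diffusion that step).

### Association acceptance (Doi scheme)

Association events between free sites within a reaction radius σ are
accepted with `p = 1 − exp(−λΔt)`, `λ = k_micro / V_σ`, where `V_σ` is the
reactive sphere (4/3)πσ³ in 3D or, for pairs confined to the membrane, the
disc πσ² with the 3D rate reduced as k₂D = k₃D/h. This volume-reaction
(Doi-style) acceptance replaces a single-particle propagator-reweighting
scheme; its merge gate is the well-mixed calibration test, which requires
the recovered macroscopic rate to match a mass-action ODE oracle within
25%.

σ defaults to 5 nm (= the bond gap) rather than a ~1 nm contact shell: at
Δt = 3 μs a free clathrin moves ≈ 9 nm rms per axis, so a 1 nm shell is
crossed ballistically and almost never sampled, while σ = 5 nm restores
adequate encounter sampling and lets freshly dissociated head-to-head pairs
(whose sites sit exactly 5 nm apart) re-enter the reactive zone — a cheap
surrogate for geminate-recombination reweighting. The calibration gate
holds for rates well below the per-step saturation limit `V_σ/Δt`; the
gated clathrin–clathrin rate at its reference value is far above that
limit and is therefore effectively diffusion-limited, as in the original
scheme.

### Placement, rejection and boundaries

A proposed association is executed by rigidly transforming the smaller (or
the cytosolic, if only one is membrane-bound) cluster into the analytic
bound pose. The event is rejected if the transformed block would leave the
closed domain [0, L]³ (any hub or site strictly outside), violate the
excluded diameter against any other clathrin, or pull a membrane-bound
AP-2 off z = 0. Ring-closing bonds inside one rigid cluster are accepted
without movement when the two sites already sit at the bond gap (±0.5 nm).

Diffusion displaces each entity (molecule or bonded cluster, moved as one
unit) by per-axis Gaussians of variance 2DΔt and rotates it about the
world x, y, z axes through its centroid by Gaussian angles of variance
2D_RΔt (extrinsic x–y–z composition; orientations are unit quaternions,
renormalised every step). Cluster coefficients follow the harmonic
composition `D = [Σ Dᵢ⁻¹]⁻¹` per axis and `D_R = [Σ D_R,ᵢ^(−1/3)]⁻³`;
any AP-2 member forces `D_z = 0` and `D_R,x = D_R,y = 0`, so membrane-bound
clusters translate and rotate only in-plane. Walls reflect: single
molecules fold per-axis (`pos → −pos` at 0, `2L − pos` at L, iterated);
rigid clusters are mirror-translated by their extreme coordinate.
Post-move clathrin overlaps are resolved by redrawing the offending
entities' moves (up to `max_retries` = 100, then the pre-move pose is
kept).

### Parameters

| parameter | default | units | origin |
|---|---|---|---|
| box edge L | 1000 | nm | one-twentieth of a HeLa cell diameter |
| Δt | 3 | μs | reference time step |
| clathrin number | 300 | — | fixed population (no synthesis/turnover) |
| AP-2 number | 150 | — | reference condition; swept 10–400 |
| k_cc gated | 50 × 0.913 | μM⁻¹s⁻¹ | reference clathrin–clathrin rate |
| k_cc free | 0 | μM⁻¹s⁻¹ | gating: no binding without AP-2 |
| k AP-2·clat | 0.0012 | μM⁻¹s⁻¹ | AP-2–clathrin association |
| koff_cc | 1 | s⁻¹ | placeholder (see below) |
| koff AP-2·clat | 1e-4 | s⁻¹ | placeholder (see below) |
| D_clat | 13 | μm²/s | reported translational coefficient |
| D_R,clat | Stokes–Einstein at r = 12.5 nm | rad²/μs | water, 298.15 K |
| AP-2 D (in-plane) | Stokes–Einstein at r = 5 nm | μm²/s | water, 298.15 K |
| σ (reaction radius) | 5 | nm | see above |
| capture height h | 10 | nm | one excluded diameter |
| counted-cluster threshold | > 10 clathrins | — | "large" clusters |

The two dissociation rates are not derivable from the main-text sources
and ship as **documented placeholders** (the config parser logs a warning
when they are left at their defaults). They were chosen for internal
consistency with the model's own phenomenology: membrane loading over 30
minutes with ~50% AP-2 occupancy requires koff_AP2 ≪ the per-AP-2 capture
rate (~6×10⁻⁴ s⁻¹), hence 10⁻⁴ s⁻¹; koff_cc = 1 s⁻¹ makes single bonds
transient but lattice members (2–3 bonds, with instant head-to-head
rebinding inside σ) long-lived, consistent with minute-scale cluster
dwell times. Both are ordinary config fields.

## Observables

Per frame, clusters are connected components of the clathrin bond graph;
a cluster is membrane-bound iff it contains ≥ 1 AP-2, and *counted* iff it
additionally has more than the threshold number of clathrins (10 at
reference scale). Membrane-bound clathrin count includes AP-2-bound
monomers. Cluster area is the convex hull of the member hubs' x–y
projections dilated by the 12.5 nm footprint disc (Minkowski sum; a
monomer is a disc of π r²). t_c is the first time the membrane-bound
count exceeds 90% of its end-of-run value (undefined when that value is
zero; analyses then fall back to the second half of the run). Pattern
statistics (frequency of each counted-cluster number, the modal "most
possible pattern", per-pattern mean areas) are computed over post-t_c
frames. Dwelling times are maximal constant runs of the counted-cluster
number; runs truncated by the window boundary are flagged censored and
excluded from means. Dwell resolution equals the frame interval (0.1 s at
reference scale) and is reported with the results.

## Synthetic data

Two generators make every stage testable without external data:

* **Initial conditions** — clathrin hubs uniform in the box with pairwise
  distance ≥ 10 nm (rejection sampling) and uniform random orientations;
  or, for stimulus protocols, a preassembled membrane lattice grown
  bond-by-bond from the analytic placement with a configurable AP-2-bound
  fraction, plus a cytosolic remainder.
* **Label masks** — non-overlapping ellipses with log-normal areas
  (mean 0.05 μm², matching the scale of measured FCL areas) at uniform
  random centres and orientations, rasterised on a configurable pixel
  grid with exact ground-truth records.

What the generators do *not* emulate: spatial correlations between real
FCLs, non-elliptical FCL outlines, curved (dome/sphere) clathrin shapes,
membrane mechanics, and crowding by other membrane proteins. Passing
tests therefore validate the simulator and its statistics, not the
biological completeness of the model.

## Scaled-down study protocol

A reference-scale run is 6×10⁸ steps (30 simulated minutes) and is
cluster-compute scale; the shipped `baseline.yaml`, `sweep_ap2.yaml` and
`egf_protocol4.yaml` configs define those runs for hardware that can
afford them. All desk-scale statistics use the protocol frozen in
`fclsim.protocols`:

* box edge 500 nm, 60 clathrins, AP-2 counts divided by 5 (number
  densities within a factor 1.6 of reference);
* the AP-2 capture/release kinetics — reaction-limited, hence freely
  compressible — scaled ×3000 so membrane loading equilibrates inside the
  run; clathrin–clathrin dissociation scaled ×10 so bond turnover is
  resolved; the gated association rate untouched (it is diffusion-limited
  already and cannot be compressed);
* 0.3 simulated seconds (10⁵ steps) per run, frames every 3 ms; the
  replicate comparisons in the test suite use 0.12 s, where pilot runs
  showed the phenotypes are already established.

This preserves the mechanism under study — AP-2 availability controls
membrane loading, and loading controls whether nothing, many small
lattices, or one giant lattice forms — while compressing the wall-clock
by ~4 orders of magnitude. Consequences to keep in mind when reading
desk-scale numbers: absolute times (t_c, dwell times) are not comparable
to reference scale, and a 60-clathrin population can host at most a
handful of >10-clathrin clusters, so the "counted cluster" threshold is
population-relative. The comparisons use:

* **scarce vs abundant AP-2** (analogues of 10 and 400): modal counted
  cluster number 0 vs 1 at the >10 threshold;
* **clathrin–clathrin rate**: reference vs 50-fold lower, counted at the
  >10 threshold (the low-rate system barely assembles);
* **clathrin diffusion**: reference vs 50-fold lower at abundant AP-2,
  counted at the population-scaled threshold (>2 of 60, the analogue of
  >10 of 300). Slow diffusion suppresses cluster merging, so the
  population fragments into several small lattices instead of coalescing
  into one giant one — at a 60-clathrin population that fragmentation is
  only expressible below the giant-cluster threshold, which is why this
  comparison (and only this one) uses the scaled threshold;
* **mean counted-cluster area** at AP-2 analogues of 100 vs 400.

Replicates use ≥ 4 seeds per condition and one-sided Mann–Whitney tests
at α = 0.05.

## Numerical choices and degenerate inputs

* Orientation quaternions renormalised after every rotational move.
* Coplanarity of bound poses is analytic (no iterative solve); tolerances
  are 1e-6 nm (coplanarity), 1e-9 (perpendicularity), 1e-9 nm (domain
  boundary; a coordinate exactly on a face is inside).
* Modal-pattern ties break toward the smaller cluster number.
* Pair candidates are visited in RNG-shuffled order each step; all
  randomness flows from one generator seeded by the run seed, so runs are
  bit-reproducible.
* Overlap resampling redraws every conflicting mobile entity; after 100
  failed rounds the entity keeps its pre-move pose.
* Degenerate inputs: an all-zero membrane-bound series makes t_c
  undefined (None) and the caller falls back to the late-run window; a
  frame with no counted clusters yields NaN mean size and is skipped in
  per-pattern averages; an empty trajectory round-trips as empty.

## Performance

The stepper is vectorised numpy (batched quaternion kernels, O(N²)
broad-phase over ≤ a few hundred molecules, memoised cluster-diffusion
composition, cluster labels cached across steps without reactions). At
the desk population (60 clathrins) it sustains ≈ 5×10⁴–10⁵
particle-steps/s on one CPU. Reference-scale runs (300 clathrins,
6×10⁸ steps) are supported but are multi-day single-CPU jobs.

## Known limitations

* The Doi acceptance under-samples encounters relative to a propagator
  reweighting scheme when diffusion per step is large compared with σ;
  absolute assembly *rates* are therefore conservative, though gated
  association remains diffusion-limited.
* Clathrin legs are rigid; no curvature transition (flat → dome →
  sphere), no membrane mechanics, no signalling reactions.
* The AP-2 pool is well mixed; real AP-2 shows membrane microdomains.
* Dissociation rate constants are placeholders (above); statistics that
  depend on them (dwell times, turnover) should be read against the
  configured values.
* Desk-scale runs compress reaction-limited kinetics; absolute timescales
  are not comparable to the 30-minute reference protocol.
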