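# Methods

## Model

`synclust` simulates nuclei of the human syncytiotrophoblast as unit-diameter
discs in a two-dimensional cross-section of the syncytial layer: a strip of
length L = 250 and mean thickness T = 1.5 nuclear diameters. The nuclear
count defaults to `target_nucleus_count(L, T, 0.294) = 140`, i.e. the number
of unit discs whose joint area is 29.4% of the mean strip — the areal nuclear
density estimated for term placenta. Dynamics are overdamped Brownian motion
with unit mobility,

    dx_i = F_i dt + sqrt(2 D dt) xi_i,

integrated with the Euler–Maruyama scheme. First-order (inertialess)
dynamics is the natural reading of "interacting Brownian motions" for
micron-scale organelles in cytoplasm; with mobility set to one, the
diffusion constant D is the only kinetic scale and fixes the time unit.

### Contact potential

Pairwise forces derive from a piecewise-quadratic potential with three
regimes (units: nuclear diameters, centre-to-centre separation x):

* x < 1 — harmonic overlap repulsion of stiffness `k_rep` (default 100),
  energy `k_rep (1-x)^2 - S`;
* 1 ≤ x ≤ 1+R — adhesive well `-S (1 - (x-1)/R)^2` of depth S ("stickiness")
  over a shell of width R = 0.05;
* x > 1+R — exactly zero.

The potential is continuous everywhere; the force has a kink at x = 1.
Only the three regimes (strong repulsion / weak adhesion / no interaction)
are scientifically specified, so a continuous piecewise-quadratic is the
simplest faithful form. `k_rep = 100` places the core two orders of
magnitude above the default well depth S = 1, making the hard core dominate
adhesion; it is kept fixed across sweeps because a stiffness that tracked
the swept S would change the core geometry between scenarios and violate
the Euler–Maruyama stability bound `k dt < 2` at dt = 10⁻³.

Walls exert the same harmonic repulsion on any nucleus centre whose
clearance falls below the nuclear radius 0.5. Clearance from the corrugated
upper membrane is taken as vertical distance — accurate because the profile
varies by at most ±0.75 diameters over a 250-diameter domain. The end walls
at x = 0 and x = L are repulsive; the domain is long enough that this
truncation is immaterial to the statistics.

### Boundary roughness

The upper membrane height is T + h(x) with h a zero-mean random profile:
a stationary Ornstein–Uhlenbeck process sampled exactly (Gaussian AR(1)
transitions, no discretisation bias) at knots every 2.5 diameters, joined
by a natural cubic spline (C¹), and multiplied by the amplitude A. The
stationary sd is 0.25 = 0.75/3 diameters so that |h| < 0.75 with 99.7%
confidence — the Gaussian three-sigma rule applied to the stated
confinement bound. The OU reversion rate (default 0.2/diameter, correlation
length 5 diameters) and the knot spacing are not scientifically pinned
down; they are configuration, and the amplitude sweep is insensitive to
them in expectation. `confinement_fraction` estimates P(|h| < 0.75) by
Monte-Carlo from independent draws of the exact stationary law (identical
marginal to path sampling, smaller Monte-Carlo error at fixed n).

### Nucleus entry

Two injection modes:

* `all` (default) — all nuclei placed before t = 0 by sequential rejection:
  x uniform (or truncated Normal(L/2, σ²) when the fusion-site spread σ is
  set), y uniform in the local channel, candidates within distance 1 of an
  accepted nucleus rejected. Failure to place raises an error naming the
  achieved count.
* `staged` — nuclei arrive at uniformly spaced times over the first half of
  the run, emulating continued cytotrophoblast fusion into the syncytium.
  After 200 rejection attempts an overlapping entry is accepted (the core
  repulsion resolves it within a few steps); a hard failure here would
  abort long-running sweeps at small σ, where the focal region saturates.

### Clustering

At snapshot times, nuclei within centre distance 1+R are connected
(inclusive threshold; ties have probability zero in simulation output).
Components of this graph are found by an iterative depth-first search with
an explicit stack — Tarjan-style, safe on 10⁴-node graphs — cross-checked in
the tests against scipy's connected components and a union-find oracle.
Reported statistics: the mass-weighted mean cluster size Σ size²/N
(expected cluster size experienced by a random nucleus, singletons
included; the unweighted mean is also exported) and censuses of clusters
with ≥2 nuclei (the model's cluster definition) and >6 nuclei (the
time-trend census).

## Scenario sweeps

Each sweep simulates `n_replicates` independent seeds per grid value
(seeds spawned from one master seed via `SeedSequence`, so the whole sweep
is reproducible) and aggregates per-value means with t-based 95% intervals.
Defaults, chosen once from a short pilot of the dynamic regimes and then
frozen:

| scenario | grid | base point |
|---|---|---|
| adhesion S | 0.2, 0.5, 1, 1.5, 2 | S = 1 |
| diffusion D (S/D fixed) | 0.002, 0.02, 0.2, 2, 8 | D = 0.2 |
| fusion-site σ | 2.5, 5, 10, 25, ∞ (uniform) | staged entry |
| amplitude A | 0, 0.25, 0.5, 1 | A = 1 elsewhere |

Rationale:

* "Maintaining the adhesiveness" across the diffusion sweep is implemented
  as S(D) = S₀·D/D₀ (constant S/D): with unit mobility D plays the role of
  temperature, so the escape probability from the adhesive well depends on
  S/D. Alternative covariation rules can be injected.
* The diffusion grid spans both regimes: at D = 0.002 a nucleus covers
  ~0.45 diameters in t_end = 50, less than the typical ~0.8-diameter gap
  (collision-limited, little clustering); at D ≥ 2 the per-step kinetics in
  the narrow shell no longer hold nuclei together (unsticking), so cluster
  size peaks in between.
* The amplitude grid stops at A = 1. The boundary is designed so that at
  A = 1 the thickness variation stays within ±0.75 < T − 1 + 0.5; beyond
  A ≈ 1 the channel pinches below one nuclear diameter in places, which
  partitions the domain into compartments — a change of topology, not of
  thickness — and the x-uniform initial placement then overcrowds thin
  regions.
* The fusion-site sweep runs staged, because entry position can only matter
  while nuclei are still entering; σ = ∞ denotes uniform entry. Sweep values
  below σ ≈ 2.5 would exceed the packing capacity of the focal region for
  all-at-start placement.
* dt = 10⁻³ keeps the RMS free step (≈0.02 diameters at D = 0.2) well below
  the shell width R and satisfies `k dt < 2` for all default stiffnesses.
  t_end = 50 is several multiples of the relaxation time of the cluster
  statistics at the base point. Replicates default to 50 (desk scale; the
  full-scale study design uses 500) — trend conclusions, not absolute
  values, are the quantity of interest, and doubling replication does not
  move the aggregated means materially.

Replicate failures are recorded and skipped, never fatal to a sweep.

The time-growth check (the median count of >6-nucleus clusters increases
over the run) is evaluated under staged entry with σ = 10: continued focal
fusion is the regime in which large clusters accumulate; with all-at-start
entry at the base stickiness the >6 census stays near zero throughout.
The census is asserted to grow net over the run with a positive time
trend, not to rise at every snapshot: being an integer count under
merging dynamics, it dips transiently whenever two large clusters merge
into one.

## Morphometry

Inputs are micron-unit centroid/radius tables (optionally with boundary
polygons and an excluded flag for condensed/apoptotic nuclei, which every
operation drops). Conventions:

* Internuclear distance is edge-to-edge: ‖c_i − c_j‖ − r_i − r_j, floored
  at 0 for overlapping profiles; nearest-neighbour values are checked
  against an exhaustive all-pairs oracle in the tests.
* "≥6 nuclei, all with nearest-neighbour distances ≤3 μm" (SNC) is
  formalised as connected components of the ≤3 μm edge-gap graph with a
  size floor of 6; in any such component every member's nearest neighbour
  is within 3 μm. A stricter variant (`strict=True`) first removes nuclei
  whose own nearest neighbour lies beyond the gap.
* SNA calls use the same construction with floor 10; the histological
  requirement that an aggregate protrude from the villus edge cannot be
  evaluated from centroids and is surfaced as a `requires_annotation` flag.
* SNA area is the convex hull of the member nucleus discs. The original
  measurements were made interactively in ImageJ without a stated rule;
  the hull convention is deterministic and configurable in principle (the
  open alternative — annotated aggregate profile area — needs images).
* Thresholds are inclusive (≤3 μm, ≥80 μm², ≥6, ≥10 nuclei).
* Density is clusters per mm² of villous field area; cytoplasmic area per
  nucleus is polygon area / nucleus count per cell.

## Synthetic data

The generator plants clusters deterministically — hexagonal packing around
cluster seeds with a prescribed intra-cluster edge gap, seeds a prescribed
distance apart — plus uniform background nuclei kept at least twice the SNC
gap from every cluster nucleus and from each other. Ground-truth labels are
returned, so recovery tests are exact whenever inter-cluster separations
exceed twice the call threshold and intra-cluster gaps stay below half of
it; a jitter option adds positional noise for robustness checks. Cell
populations mix mononucleate cells with k-nucleate syncytia inside square
polygons of known analytic area. Particle areas are lognormal (defaults
log-mean 5.55, log-sd 0.55, putting ~95% of mass in ≈85–775 μm² — the
right-skewed, sub-900 μm² range typical of SNAs).

What the generator does not emulate: real nuclei are not perfect discs;
real cluster geometry is irregular rather than hex-packed; real boundaries
are not rectangles; segmentation and staining noise are absent. Passing
recovery tests therefore demonstrates correctness of the measurement rules
on unambiguous geometry, not robustness to imaging artefacts.

## Numerical choices and degenerate inputs

* Exact OU transition sampling; natural cubic spline through the knots.
* Inclusive adjacency at exactly 1+R and at the 3 μm / 80 μm² thresholds.
* A = 0 short-circuits to an exactly flat membrane without consuming
  random numbers.
* Zero-diffusion runs are deterministic gradient flows; overlapping pairs
  relax apart monotonically and residual overlap after relaxation is below
  0.02 diameters at the default stiffness.
* Non-finite positions abort a run with the offending nucleus and dt named;
  within sweeps such failures are recorded per replicate.
* Empty patterns, single-nucleus distance requests, zero field areas and
  non-simple polygons raise informative errors.

The integrator's hot loop is JIT-compiled (numba) and exploits the
quasi-one-dimensional strip: nuclei are sorted by x each step and pair
search stops at the interaction radius, giving O(n log n) work per step.
The same compiled path, with all forces disabled, reproduces free diffusion
(per-coordinate displacement Normal(0, 2Dt); MSD = 4Dt), which the tests
verify against the closed form.

## Known limitations

* 2D cross-section only; no nucleus deformation, hydrodynamics, shedding
  or apoptosis.
* The absolute scales of S, D and the authors' parameter grids are not
  published; sweep conclusions are trend-level, not curve-level.
* The interior maximum of the diffusion sweep reflects finite-horizon
  kinetics and the finite-step unsticking of the shell at large D; the
  peak location depends on dt and t_end, though its existence does not.
* Staged entry accepts an overlapping placement after 200 failed attempts,
  transiently violating the hard-core constraint at small σ.
* Morphometric conventions (hull area, inclusive thresholds, graph-based
  SNC rule) are documented choices where the original image-analysis
  procedure was manual.
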