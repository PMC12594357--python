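# Methods

This note documents the models, the numerical choices and the study
conditions used by the test suite, in the package's own terms.

## Geometry

### Conventions

Voxels are indexed `(i, j, k)`, 0-based, with `k` the depth axis
("planes" are constant-`k` slices). The pore phase is 26-connected and the
background 6-connected — the standard dual pair without which the discrete
topology tests are unsound. The array border is background. All geometry is
computed in voxel units; the physical resolution (µm per voxel edge) enters
only on export and when converting diffusion coefficients. This keeps the
discrete topology code free of float drift.

### Euler characteristic

`euler_characteristic` counts the cells of the cubical complex spanned by
the closed unit cubes of the pore voxels: χ = V − E + F − O. For the
26-connected object this equals #components − #tunnels + #cavities (e.g.
solid cube 1, solid torus 0, cube with a concentric cavity 2).

### Homotopic thinning

A pore voxel is deleted when (i) it lies on the boundary, (ii) it is not an
ending point (≥2 neighbors), (iii) its removal preserves χ and (iv) the
number of 26-components. (iii)+(iv) are evaluated on the 3×3×3
neighborhood. Because every cell of a voxel is shared only with its
26-neighbors, the local χ change equals the global one *exactly*; the local
component condition is the classical T26 connectivity condition. The
conjunction agrees voxel-for-voxel with the independent T26/T6 simple-point
characterization (verified exhaustively on random volumes in the test
suite).

A caution for anyone tempted to replace the local test with a global
recomputation: preserving the *global* Betti numbers (object components,
background components, χ) is strictly weaker than simplicity. There exist
voxels whose removal changes the topology locally while compensating
changes reconnect elsewhere, leaving every global Betti number unchanged;
the test suite contains machinery that found such counterexamples on random
9³ volumes. The local test is the correct homotopy-preservation criterion
and is what the thinning uses.

**Visiting order.** The result of thinning depends on the order in which
boundary voxels are visited. Each pass collects the current boundary
voxels and processes them ordered by (distance shell of the original
volume, fewest remaining pore neighbors, lexicographic), deleting
sequentially against the already-updated volume until a fixed point. The
shell+exposure ordering keeps the erosion front centered: visiting in raw
lexicographic order can strand a convex corner voxel at degree one mid-pass
(ending protection then freezes a one-voxel spur onto an otherwise clean
curve — observed on the torus fixture). The chosen order is deterministic,
so skeletons are reproducible bit for bit. Ending-point protection applies
from the first pass, so isolated voxels and single-voxel components
survive (homotopy).

No branch pruning or λ-simplification is performed: in water-filled porous
media small features still carry diffusive flux, so simplification is a
modelling decision the user must make explicitly, not a default.

### Branches, partition, graph

Branches are the 26-components of the simple (degree-2) skeleton voxels.
Ending voxels join their unique adjacent branch; junction voxels join the
adjacent branch with the smallest id (clusters are absorbed iteratively);
skeleton components with no simple voxel (isolated voxels, two-voxel
components, tiny "+" junctions) each become their own branch. Final branch
ids are ordered by each branch's lexicographically smallest voxel. Note
that with axis-aligned arms the first voxels of two arms are mutually
26-adjacent, so junctions are generally *clusters*, not single voxels.

Every pore voxel is assigned to the nearest branch (Euclidean distance
between voxel centers, over all voxels of the branch). The assignment
iterates branches in ascending id with an exact distance transform each,
keeping strictly smaller squared distances; squared distances are integers,
so ties resolve exactly to the smallest branch id. Nearest-sets that come
out disconnected (possible because Euclidean distance cuts across the
background, e.g. between the legs of a U-shaped pore) are split into their
26-components; each split is logged. The result is an exact partition of
S: no voxel lost, every region connected.

The region adjacency graph is built in one pass over the label image,
inspecting only the three positive-direction neighbors of each voxel, so
each 6-adjacent pair is counted once. Arcs require shared faces —
edge/corner contacts carry no area and create no arc. Contact areas are
stored as integer face counts (µm² only on export). Centroid distances are
floored at one voxel (interlocking regions can bring inertia centers
arbitrarily close, and the diffusion coupling divides by this distance);
the floor is logged when applied.

## Biology and transport

### Pools and transformation

Per node: b1 = microbial biomass, b2 = DOM, b3 = SOM, b4 = FOM, b5 = CO₂
(µgC); DOM concentration c = b2/v with v the region volume. One explicit
transformation step moves, per δt: Monod growth v_DOM·c/(κ_b+c)·b1·δt from
DOM to MB; mortality µ·b1·δt split β to DOM and (1−β) to SOM; respiration
ρ·b1·δt to CO₂; hydrolysis v_SOM·b3·δt and v_FOM·b4·δt to DOM. All fluxes
use start-of-step values; the five increments cancel pairwise, so total
carbon is conserved to machine precision. A step that would drive any pool
negative raises an error naming the node and the admissible δt bound —
clamping would silently destroy conservation.

Default parameters (the Arthrobacter sp. 9R DOM-degradation set commonly
used in pore-scale studies): v_DOM = 9.6 d⁻¹, ρ = 0.2 d⁻¹, µ = 0.5 d⁻¹,
β = 0.55, v_SOM = 0.001 d⁻¹, v_FOM = 0 (FOM excluded from the default
scenarios; SOM starts at 0 and builds up from mortality). κ_b is a DOM
concentration and must be given in scenario units (µgC/voxel³ internally).

Unit regime: rates in day⁻¹, δt in seconds (converted internally,
1 d = 86 400 s), D_c in voxel²/day (`dc_voxel2_per_day` converts from
cm²/s given the resolution; DOM in water, 6.73·10⁻⁶ cm² s⁻¹, is ≈10⁵
voxel²/day at 24 µm voxels), volumes in voxel³, masses in µgC.

### Diffusion on the graph

Only DOM diffuses. Per arc, Θ_ij = α·D_c·s_ij·δt/d_ij is an exchange
volume; α (the diffusive overall conductance, a single scalar in (0, 1])
multiplies the Fick flow between regions and is applied identically in both
schemes, since the calibration below fixes it for the model as a whole.

* **Implicit (backward Euler).** Solves (diag(v) + L)c' = v∘c with L the
  Θ-weighted graph Laplacian — symmetric positive definite (asserted), zero
  column sums, hence mass-conserving and obeying the maximum principle.
  Solved by Jacobi-preconditioned conjugate gradient, relative tolerance
  1e-12 (configurable), max 10·p iterations, followed by one round of
  iterative refinement; the refinement keeps the per-step mass drift near
  machine precision, so thousand-step schedules stay within 1e-9 relative.
* **Explicit (forward Euler).** c'_i = (1 − ΣΘ_ij/v_i)c_i + ΣΘ_ij c_j/v_i,
  rejected with the admissible δt named when max_i ΣΘ_ij/v_i > 1. Used to
  validate the implicit time step: the two schemes must converge to each
  other as δt shrinks.

The per-step operator difference between the schemes is M²δt² (M the
volume-scaled Laplacian), so at a fixed horizon their gap is asymptotically
linear in δt: refining 240 s → 30 s gives a factor-8 gap reduction in the
smooth regime. Ratios beyond 8 appear only when the stiffest mode matters;
a one-step analysis bounds the achievable 240 s/30 s ratio near 11 at the
stability limit. The convergence test therefore probes that regime: the
coarsest step sits at 95% of the explicit stability bound and the initial
DOM is placed on the stiffest node (largest ΣΘ/v), mimicking an injection.

### 0D baseline and placement

`ode0d` iterates the same transformation update on the aggregate masses
with the total pore volume as v. With uniform DOM concentration and
biomass proportional to node volume, diffusion is a no-op and the
spatialized totals reproduce the 0D model step for step — a structural
identity used as a test. Clustered placements (`spots` mode: distinct
nodes sampled proportionally to volume, equal or weighted masses) depart
from the 0D model because spots deplete their local DOM and become
diffusion-limited; the departure grows with spot sparsity, and is mild when
most nodes carry a spot. With DOM-rich initial conditions (κ_b well below
the initial concentration) all pools eventually drain into CO₂; note that
the Monod equilibrium leaves a DOM residue c* = κ_b·(ρ+µ)/(v_DOM−(ρ+µ))
≈ 0.079·κ_b below which biomass can no longer sustain itself, so with κ_b of the
order of the initial concentration a visible DOM fraction is never
respired. The long-run scenario in the tests uses κ_b/c₀ = 0.02.

## Conductance calibration

The plane-injection benchmark places a known DOM mass in the first two
constant-k planes (spread over regions by their voxel count there), runs
diffusion only, and compares the per-plane mass profile of the graph model
against a voxel-level reference: explicit 6-neighbor finite differences on
the full pore grid with no-flux walls, sub-stepped to respect the D_c·δt ≤
1/6 stability bound. Both producers conserve mass exactly. The voxel
reference solves the same diffusion equation the graph model coarsens, so
it serves as the ground truth in place of heavier voxel-scale simulators.
`calibrate_alpha` grid-searches α (default 0.05…1.00 step 0.05) and scores
each profile by Pearson correlation (scale-invariant; sum of squared
errors available as an alternative), optionally over a plane range.

On a straight tube pre-segmented into equal slabs — a geometry where the
region model is exact — the calibrated optimum reproduces the voxel
profile with correlation > 0.99 and < 5% relative L1 error, and planting a
reference generated by the graph model itself recovers the planted α with
score 1. On real pore geometries the optimum is genuinely below 1 because
region centroid distances overestimate the effective diffusion path.

## Synthetic fixtures

Generators produce shapes with known topology: solid tubes (χ = 1; strict
lattice-disk cross-section so radius 1 degenerates to a line; optional
flush axial ends for injection benchmarks), solid tori (χ = 0), planar
Y-junctions of three tubes at 120° (χ = 1, three skeleton endings), a cube
with a concentric cavity (χ = 2), and correlated random porous media
(seeded Gaussian-filtered white noise thresholded at the quantile matching
the target porosity, achieved to within one voxel count). These emulate
the connectivity and porosity range of real CT pore spaces (roughly
8–57%), not their full morphology: no grain packing, no anisotropy, no
imaging noise. Tests passing on them establish the correctness of the
discrete geometry and the numerics, not image-processing robustness.

## Problem sizes used by the test suite

Topology suite: ten 64³ random media (plus the shaped fixtures);
oracle suites: ≤13³ for the per-voxel simple-point comparison, 16³ for the
graph scan, 18³ for the nearest-branch scan; conservation and convergence:
a 100-node random graph, 1000 and 480-step schedules; spatialization: a
64³ medium giving ~1600 regions, 1000 biomass spots, five simulated days at
δt = 120 s; calibration: a radius-4, length-64 tube in 8 slabs. These
sizes exercise every code path while keeping the suite fast.

## Known limitations

* Pores are assumed water-filled; no partial saturation or water films.
* A single microbial population; no motility, no pore-space evolution
  during the dynamics.
* α is a single scalar; per-arc conductances (shape-dependent) are out of
  scope.
* The geodesic-distance variant of the partition (which would avoid
  cross-background captures) is not implemented; splitting handles those
  cases instead.
* Thinning visits voxels in one fixed order; other orders yield other
  (equally valid) skeletons for highly symmetric shapes.
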