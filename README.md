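# skelpore

Curve-skeleton partitioning of 3D pore space and graph-based simulation of
microbial organic-matter mineralization in porous media (soils imaged by
micro-CT being the motivating case).

## The problem

Simulating microbial carbon turnover directly on the voxel grid of a
micro-CT image (tens to hundreds of millions of voxels) is accurate but
very expensive. Approximating the pore space with geometric primitives
(maximal balls, ellipsoids) is fast but loses 5–20% of the pore voxels at
region edges. `skelpore` takes a third route: it partitions the pore set
**S** into connected regions built from the branches of its curve skeleton.
The partition covers S exactly — no voxel is lost, contact surfaces between
pores are exact — while the resulting graph is typically 10–20× smaller
than a ball network of the same image.

The pipeline:

1. **Curve skeleton** of S by homotopic thinning. A boundary voxel is
   deleted only if it is not an ending point and its removal preserves the
   Euler characteristic χ and the number of 26-connected components
   (a simple-point test on the 3×3×3 neighborhood); erosion passes repeat
   to a fixed point.
2. **Branches**: skeleton voxels are *ending* (1 neighbor), *simple* (2) or
   *interior* (>2); a branch is a maximal 26-connected set of simple
   voxels.
3. **Partition**: every pore voxel joins its Euclidean-nearest branch;
   disconnected nearest-sets are split, so the label image L is an exact
   partition of S into connected regions (pores).
4. **Attributed relational graph**: one node per region (inertia center,
   volume), one arc per face-adjacent region pair (contact area s_ij in
   voxel faces, centroid distance d_ij). The Global Connectivity Indicator
   is GCI = #arcs / #nodes.
5. **Biological dynamics** on the graph: five carbon pools per node —
   microbial biomass (MB), dissolved (DOM), soil (SOM) and fresh (FOM)
   organic matter, and CO₂ — with Monod growth on DOM
   (v_DOM·c/(κ_b+c)), mortality split β : (1−β) between DOM and SOM,
   respiration ρ, and first-order hydrolysis of SOM/FOM. Each time step
   splits the operator: the local transformation update, then DOM diffusion
   along arcs with exchange volume Θ_ij = α·D_c·s_ij·δt/d_ij, solved
   backward-Euler (conjugate gradient; unconditionally stable) or
   forward-Euler (with a stability guard). α is the *diffusive overall
   conductance*, a single scalar calibrated against a voxel-level
   finite-difference diffusion reference on a plane-injection benchmark.

A non-spatialized 0D baseline (the same transformation update applied to
the aggregate masses) quantifies what the spatial structure adds.

## Worked example

Build a Y-shaped pore volume, run the full geometric pipeline and print the
summary:

```bash
skelpore pipeline --kind y_junction --size 24 --out-dir out/
```

```json
{
  "arcs": 3,
  "branches": 3,
  "ending_voxels": 3,
  "euler_characteristic": 1,
  "gci": 1.0,
  "interior_voxels": 1,
  "pore_voxels": 410,
  "regions": 3,
  "skeleton_voxels": 35
}
```

The three tubes of the junction yield a skeleton with 3 ending voxels and
one junction voxel, hence 3 branches and 3 regions whose union is all 410
pore voxels; the 3 arcs connect each pair of regions that share a contact
surface, giving GCI = 3/3 = 1. On a correlated random porous medium the
same command scales up (48³ at 35% porosity: 38 707 pore voxels → 1 520
skeleton voxels → 295 regions, 724 arcs, GCI ≈ 2.45).

From Python, the same objects compose directly:

```python
import skelpore as sp
vol = sp.synthetic.make_random_porous((48, 48, 48), 0.35, seed=3)
skel = sp.curve_skeletonize(vol)
part = sp.assign_regions(vol, sp.segment_branches(skel))
graph = sp.build_graph(part)

params = sp.BioParams(dc=1e4, alpha=0.35, dt=30.0, k_dom=1e-4)
state = sp.BioState.zeros(graph.volumes)
state.b[0] = sp.place_initial_biomass(graph, 0.18, n_spots=100, mode="spots", seed=1)
state.b[1] = sp.uniform_dom(graph, 2.0)
result = sp.simulate(graph, state, params, duration=5 * 86400)
print(result.percent_of_initial().tail(1))
```

which reports the five pool totals as percent of the initial carbon after
five simulated days.

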