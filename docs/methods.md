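# Methods

This note describes the registration model, the optimizer, the refinement
loop and the multi-view pipeline implemented by `wolfreg`, together with
the numerical design choices and their rationale.

## 1. Transform model

A candidate alignment is a 15-parameter affine transform

```
H(p) = T(tx,ty,tz) · S(sx,sy,sz) · R(phi_x,phi_y,phi_z) · SH(sh1..sh6)
```

composed of a translation, an anisotropic scaling, an extrinsic XYZ
rotation (angles in degrees) and a shear matrix with unit diagonal and six
off-diagonal coefficients.  Points are row vectors; a cloud `Q` (N×3)
maps as `Q·H[:3,:3]ᵀ + H[:3,3]`.  `compose_matrix_batch` builds the (K,4,4)
stack for a whole population with vectorized trigonometry; the linear
block is `(S·R)·SH` with `S` scaling the rows of `R`.  Inversion solves
the 3×3 linear block directly and raises `DegenerateTransformError` on a
singular block.

The default search box (`DEFAULT_BOUNDS`): translations ±1.5, angles
±45°, scales in [0.8, 1.2], shears ±0.5.

## 2. Objective

The registration fitness is the asymmetric nearest-neighbour MSE

```
f(p) = (1/N) Σ_j min_i || q_j·H(p)ᵀ − target_i ||²
```

with exact Euclidean nearest neighbours, no trimming, no distance cap and
ties broken toward the lowest target index.  The target's spatial index is
built once per cloud pair and reused across every fitness evaluation.

Two nearest-neighbour backends honour the same exactness contract: a
numba-compiled k-d tree (median split on the widest dimension, per-node
bounding boxes, branch-and-bound pruning) and `scipy.spatial.cKDTree` as a
fallback.  The compiled kernel is ~2–4× faster on the batched queries this
workload produces, including far-from-target queries generated by
opposition jumps, which is where generic trees degrade.  Population
evaluation (`RegistrationObjective.batch`) transforms all N source points
under all K candidate matrices with a single BLAS product
`(N,3)@(3,3K)` before one batched NN query.

## 3. Coarse optimizer

A pack of K wolves (default 100) runs T iterations (default 2000).  Each
iteration:

1. **Leader pull.**  Wolves rank by fitness (stable sort, ties to the
   lower index); the best three are alpha, beta, delta.  Each wolf forms
   three pulled positions `x_i = leader_i − A_i·D_i` where
   `D_i = |C_i·leader_i − x|`, with per-leader control vectors
   `A = 2a·r − a` and `C = 1 + (2r−1)c²`.  The alpha distance is further
   scaled by a per-wolf sine/cosine factor `r₁·sin(r₂)` or `r₁·cos(r₂)`
   (fair coin).  The candidate is the weighted sum `w₁x₁ + w₂x₂ + w₃x₃`.

   Schedules: `a(t) = 2·((T−t)/T)^mu` (nonlinear decay, exponent `mu`
   configurable, value 2 at t=0 and 0 at t=T) and `c(t)` decaying linearly
   from 1 at t=1 to 0 at t=T.  The weights are
   `w₁ = cos θ`, `w₂ = ½ sin θ cos φ`, `w₃ = 1 − w₁ − w₂` with
   `φ = ½·arctan t` and `θ = (2/π)·arccos(⅓)·arctan t`, so the pull starts
   alpha-dominated (w₁→1 as t→0) and converges to equal thirds; the sum is
   exactly 1 and `w₁ ≥ w₂ ≥ w₃` for all t ≥ 1.  (w₃ is marginally negative
   for small t; the identities above are the contract.)

2. **Behaviour consideration.**  A per-wolf scalar `A = 2a·r − a` selects
   exploration (|A| > 1) or exploitation (|A| ≤ 1).  Exploring wolves add
   heavy-tailed Lévy steps
   `step_j = η_j·α_j·(u_j/|v_j|^{1/β})·(x_j − x_alpha,j)` (Mantegna
   construction, β = 1.5, per-dimension scale `α_j = L_j/(10·t·d)` with
   `L_j` the box width) either once on the weighted pull or once per
   leader pull before weighting (fair coin).  Exploiting wolves jump to a
   random-opposition point of their personal best,
   `lb + ub − r·x_best`.  The candidate replaces the stage-1 candidate
   only on strictly better fitness.

3. **Dimensional learning.**  Radius `R = ||x − x_candidate||` defines a
   neighbourhood (all pack members within R of the wolf; if none other
   than the wolf itself, its single nearest other wolf).  Per dimension,
   `cand_j = x_j + r_j·(x_neigh,j − x_pack,j)` with fresh neighbourhood and
   pack draws per dimension.  Again accepted only on strict improvement.

4. **Greedy update.**  The wolf keeps its previous position unless the
   surviving candidate strictly improves its own fitness, so per-wolf and
   global-best fitness are non-increasing by construction; the personal
   best therefore always equals the current position.

All candidates are clipped to the search box.  All randomness flows from
one seeded generator, making runs bit-reproducible.  The loop evaluates
fitness in exactly three population batches per iteration.

Two deliberately configurable readings of under-specified details:
`sca_angle_mode` ("literal": sine/cosine angles drawn from U[0,1] radians,
the default; "scaled": U[0,2π]) and `levy_alpha_mode` ("hyperbolic"
`L/(10·t·d)`, the default; "exponential" `L·10^(−t·d)`, which underflows
within a few iterations and is kept only for comparison).

## 4. ICP refinement

The coarse optimum is polished by alternating (i) freezing the
nearest-neighbour correspondences at the current parameters and (ii)
minimizing the resulting smooth frozen-correspondence MSE over all 15
parameters with an adaptive Nelder-Mead simplex (explicit initial simplex,
absolute function tolerance 1e-30, one restart from the best point with a
simplex shrunk 1000×).  Outer rounds that fail to strictly improve the
*true* MSE are rejected, so refinement never worsens the starting fitness;
the loop also stops once a round fails to at least halve the MSE
(diminishing returns), which keeps total cost bounded without giving up
precision — on exact synthetic pairs the refined MSE reaches ~1e-32.
Refined parameters are unconstrained: polishing may step slightly outside
the coarse search box.

## 5. Multi-view registration

F ordered views merge bottom-up.  Level 1 registers every consecutive
pair (later view = source, earlier = target).  Survivors then merge either
in a balanced binary tree ((1,2),(3,4),(5,6) → … → one cloud, re-running
the full registration between merged survivors) or as a left-to-right
chain; the topology is configurable because either reading is defensible.
The final MSE is the registration MSE of the last merge.

Partial overlap is the crux: the objective has no outlier rejection, so
source points without a true counterpart bias the optimum.  Three
mechanisms address this:

* **Pre-sampling** (`overlap_sample`): keep ⌈fraction·N⌉ random points,
  then one representative (centroid-nearest member) per occupied voxel
  (default voxel: bounding-box diagonal / 50).
* **Voxel-hull overlap** (`voxel_overlap`): before registration, keep only
  points whose voxel is occupied by both clouds.  This requires the
  inter-frame misalignment to be smaller than the voxel, and still keeps a
  boundary band of strays one voxel wide.
* **Aligned-frame overlap refinement** (`refine_overlap`): after the
  coarse+ICP pass, map the source through the estimate, re-evaluate mutual
  voxel occupancy in the (nearly) common frame with progressively smaller
  voxels (diagonal/50, /150, /400, /1000) and re-polish with ICP on the
  cleaned subsets.  Each pass must not worsen the median squared
  nearest-neighbour distance over the full clouds — a validation score
  robust to up to half the points being strays — otherwise it is rejected
  and the ladder stops.  On synthetic slab fixtures this removes the stray
  bias entirely (pairwise matrix error ~1e-16 instead of ~1e-2).

## 6. Synthetic fixtures

`shapes.make_cylinder` and `shapes.make_pyramid` sample closed surfaces
uniformly by area.  `make_pair` keeps the shape as the target and pushes
the same points through a fixed in-bounds affine matrix (printed to six
decimals, with its inverse) to form the source: because point identities
are shared, an exact alignment with MSE 0 exists and the recoverable
transform is known in closed form.  `make_slab_views` cuts a cloud into
overlapping z-slabs, each perturbed by a small random affine, emulating
consecutive partial scans with known ground truth.

Slab-fixture design notes: the *pyramid* is used for multi-view tests
because a cylinder slab is nearly rotation-invariant about its axis,
which creates spurious low-fitness basins at rotated alignments inside
the ±45° search box; the pyramid's cross-section tapers with height and
its only discrete symmetry (90°) lies outside the box.  Perturbation
magnitudes (translations ≤ 0.01, rotations ≤ 0.5°) are derived from the
voxel co-occupancy requirement above (worst-case inter-frame displacement
≈ 0.035 < the ≈ 0.06 selection voxel), not tuned empirically.

## 7. I/O

Cloud formats are deliberately narrow and text-only: ASCII PLY restricted
to x/y/z vertex properties, whitespace XYZ and CSV, written as float64 at
17 significant digits so write/read round trips are exact to well below
1e-9.  Binary PLY is recognized and rejected with a clear error rather
than misparsed; parse errors name the offending line.  Run reports are
JSON, and the stored MSE is recomputed against the stored parameters at
save time (a mismatch beyond 1e-12 relative raises).
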