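# Methods

## Problem and model

`resectplan` plans en-bloc resections of bone tumors. Input is a pair of
watertight triangulated surface meshes in a shared millimeter frame — the
bone and the tumor, as produced upstream by image segmentation (which is out
of scope here). The package discretizes the scene into a uniform grid of
cube-center points (default pitch 2 mm), labels each center **healthy bone**
(inside bone, outside tumor), **intracortical tumor** (inside both), or
**extraosseous tumor** (inside tumor only), and then searches for the cut
surface that removes the whole tumor with the least collateral healthy bone.

The cut families are built from one construction. A parameter vector
(θ_z, θ_y, θ_x, t_x, t_y, t_z[, φ_z]) defines a local frame: the scene is
rotated about the fixed base axes in z, y, x order (extrinsic, degrees,
right-handed), then translated so that the focal point **FP** is the local
origin below the tumor. The cut surface is the quasi-conical sheet of rays
from FP through the convex hull of the tumor vertices T′, **carried past
the tumor and out through the far cortex**: the resected piece must be
withdrawable en-bloc along the cone, so the cut traverses the whole bone
and every healthy voxel inside the cone counts as collaterally removed.
(Truncating the cone just beyond the farthest contained bone point, as the
exported surface does, leaves the count unchanged.)

* **conical** — the extended cone itself.
* **flat-based** — the cone tip is replaced by a planar facing cut at the
  lowest tumor z in the local frame; healthy voxels with z ≤ min(T′_z) are
  retained (strict comparison on the removed side).
* **contoured** — after an extra rotation φ_z about the local z axis, the
  tip is instead trimmed by a curvilinear cut: only voxels whose (x, z)
  projection falls inside the 2D convex hull of the projected tumor are
  removed.

By construction the removed region always contains every intracortical
tumor voxel (the cone contains the hull, which contains the tumor; the
facing cuts never cut into the tumor), and for identical parameters the
three removed sets nest: contoured ⊆ flat ⊆ conical. The carried-through
cone is also what makes the facing cuts matter: the conical family must
exit on *both* sides of the tumor, while the flat and contoured families
retain the bone behind the facing cut — this is why their optimized waste
is systematically lower, and why the orientation search trades the cone's
exit path against its opening angle.

The objective is **bone waste**

    waste % = 100 · removed / (removed + intracortical),

the share of the resected intracortical volume that is healthy bone. Voxel
counts stand in for volumes (count × pitch³). Extraosseous tumor is excluded
from the denominator — it lies outside the bone, so it neither costs nor
saves bone stock; both conventions (intracortical-only and whole-tumor
denominators) are emitted in every serialized `WasteResult` so either can be
reported.

Margins are modeled by uniform scaling of the tumor mesh about its centroid
(`expand_margin`, scale ≥ 1); the resection is then planned against the
inflated tumor while the original is retained for reporting.

## Parameter bounds

| variable | meaning | bounds |
|---|---|---|
| θ_z, θ_y, θ_x | base-axis rotations | ±180° |
| t_x, t_y | focal point under the tumor footprint | rotated tumor x/y extents |
| t_z | focal point depth | [−200 000, min(T′_z)] mm |
| φ_z | local z rotation (contoured only) | ±90° |

The −200 000 mm lower bound is a numerical stand-in for −∞: a focal point
that far away yields a quasi-cylindrical cut. The translation bounds are
defined in the *rotated* frame and therefore move with the rotation
variables; since the swarm optimizer needs a fixed box, the static box uses
the tumor's circumscribing radius and every candidate is clamped to the
exact bounds of its own rotation before evaluation.

## Numerical choices

**Voxelization** casts one vertical ray per grid column and classifies by
crossing parity. Crossings are found per triangle from 2D barycentric
coordinates; a hit within 1e−10 (barycentric) of an edge or vertex, or a
triangle nearly parallel to the ray, marks the column ambiguous, and those
few points are re-cast with a randomly tilted direction (full
Möller–Trumbore, up to 8 tries) until the hit is clean. A point within
1e−9 mm of a surface counts as *inside* — ties always favor resection
completeness. The grid is anchored with the minimum corner of the joint
bounding box on a cube corner, centers at min + pitch·(k + ½): a
deterministic, reproducible phase. Count-based volumes carry an O(surface ·
pitch) phase sensitivity; for solids ≥ 20 mm across at pitch 2 the error is
within ±3% at generic placements, while exactly lattice-symmetric
placements (a sphere centered equidistant from eight cube centers) are a
worst case that can reach ~5%. Validation scenes therefore place analytic
solids at a fixed generic offset, as segmentation output always is.

**Cone membership** is never computed by running a hull code on the raw
point set T′ ∪ {FP}: with |t_z| up to 2·10⁵ the apex coordinate would
dwarf the millimeter-scale tumor detail. Instead we use the identity

    p ∈ cone(FP, conv(T′))  ⇔  ∃ t > 0 : FP + t(p − FP) ∈ conv(T′)

(with t ≥ 1 the same test gives conv(T′ ∪ {FP}) itself), which reduces
membership to intersecting one interval per hull facet of conv(T′) alone —
tumor-scale, well-conditioned, exact at any apex distance, and fully
vectorized over voxels. Facet inequalities use a 1e−9 boundary-inside
tolerance. The evaluation is cross-checked in the tests against a
conic-combination LP-feasibility oracle per voxel (the cone from the
origin over conv(T′) is exactly the conic hull of the tumor vertices). A
conservative prefilter — forward half-space plus distance to the
apex–centroid line bounded by R·|p|/(d−R), with R the tumor's
circumscribing radius and d the apex–centroid distance — skips voxels that
provably cannot be in the cone.

**Profile export.** Counting uses the cone membership test directly; the
exportable cut surface is built separately. `extend_profile` lengthens each
focal-point→hull-vertex ray beyond the farthest bone/tumor point inside the
cone plus a configurable clearance (default 5 mm), so the exported sheet
clears the cortex; the voxel count — which already includes everything
inside the cone up to that farthest point — is unaffected. The facing cut is exported as the
cone cross-section polygon at the base plane (flat) or the projected 2D
hull loop (contoured); the exported triangulation is a visualization aid,
not the counting geometry, and `resectplan verify` re-counts every reported
number from the stored parameters instead of the exported triangles.

## Optimization

Bone waste is minimized per cut family with bounded particle-swarm
optimization:
50 particles, personal and global learning coefficients 1.49, per-particle
inertia initialized uniformly in [0.1, 1.1], an iteration cap of
200 × n_parameters, early termination after 20 iterations without
improvement of the global best (relative threshold 1e−12), and 10
independent restarts whose generators are spawned from (seed, restart
index) — making results reproducible and invariant to restart order.

Details that a generic PSO leaves open are fixed explicitly: inertia is scaled ×1.25 (capped at 1.1) after an
iteration that improves the global best and ×0.75 (floored at 0.1) while
the swarm has stalled for ≥ 2 iterations; velocities start at zero;
positions are clamped to the box with the violating velocity component
zeroed. Evaluations are memoized on parameter vectors quantized at 1e−6.
Degenerate-hull evaluations receive +∞ cost and the search continues.
Warm-starting flat/contoured swarms from the conical optimum is available
but off by default — it risks premature local convergence.

Because the objective is a voxel count it is piecewise constant; the
20-iteration stall rule therefore terminates runs long before the iteration
cap on desk-scale scenes.

A planar comparator (`best_planar_baseline`) stands in for manually planned
single-plane resections: normals on a Fibonacci covering of the sphere,
with the per-normal offset set analytically just below the tumor's support
value (for a fixed normal the feasible offset minimizing removed bone is
unique, so no offset grid is needed).

## Synthetic phantoms

Patient data is not shipped; the `phantom` module generates watertight
long-bone-like scenes with known analytic geometry. The bone is a
generalized surface of revolution r(θ, z) = max(tapered shaft profile,
superellipsoid-like condylar bulge with a mild bicondylar cos 2θ
modulation) — closed and star-shaped about the shaft axis by construction.
Tumors are icospheres with a radial scaling field: spheres, ellipsoids, or
lobed solids whose radius is modulated by seeded spherical harmonics of
degree 2–4 (coefficients ~N(0, 0.55/ℓ), clipped to [0.4, 1.9] of the base
radius so the solid stays star-shaped about its centroid, which keeps
margin expansion containment-preserving).

`make_suite` spans tumor size classes (0.45/0.60/0.78 of the shaft radius),
centered vs eccentric placement, and cortex-breaching vs contained cases.
Most suite tumors are lobed on purpose: real segmented tumors are
irregular, and the gap between a tumor and its convex hull adds a second,
shape-driven component to the waste on top of the unavoidable exit-path
component; one sphere and one ellipsoid are kept as convex controls.

Default problem sizes (shaft radius ~13–16 mm, length ~70–90 mm, tumors
5–11 mm radius, pitch 2 mm) give scenes of roughly 3 000–15 000 healthy-bone
voxels — a desk-scale stand-in for segmented knee-region patient anatomy,
with optimization runs of seconds per cut family.

What the phantoms do **not** emulate: cortical/trabecular distinction,
segmentation and smoothing artifacts, anisotropic image resolution, soft
tissue and critical structures, and anatomically realistic condyle shapes.
Passing tests on phantoms therefore validate the geometry and optimization
machinery, not clinical performance on patient anatomy.

## Known limitations

* Waste is voxel-counted; sub-voxel accuracy of the cut surface is not
  assessed, and very thin bone shells below the pitch are invisible.
* The exported cut-surface triangulation joins profile and facing loops
  with simple panels; it is faithful near the counting geometry but not
  guaranteed self-intersection-free for extreme parameter vectors.
* The planar comparator is a geometric baseline, not a surgeon; reported
  improvements over it are not clinical claims.
* Structural integrity of the remaining bone (e.g., finite-element
  assessment) is outside the scope of the optimization objective.
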