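# resectplan

Automated planning of **en-bloc bone tumor resections** with convex-hull cut
geometries, for surgical-planning researchers and engineers working on
robot- or guide-assisted orthopedic oncology.

Conventional preoperative plans are a handful of manually placed planar
cuts. A robot or patient-specific guide can follow a more elaborate, ruled
cut surface that conforms to the tumor — removing far less healthy bone.
`resectplan` generates and optimizes such surfaces from segmented anatomy:

1. **Voxelize** watertight bone and tumor surface meshes (STL/PLY, mm) into
   a uniform cube-center grid (default 2 mm pitch) labeled
   *healthy bone* / *intracortical tumor* / *extraosseous tumor*, and center
   the scene on the tumor centroid.
2. **Build a resection geometry (RG)** from a small parameter vector
   (θ_z, θ_y, θ_x, t_x, t_y, t_z [, φ_z]): rays from a focal point FP
   through the tumor's convex hull, carried out through the far cortex so
   the piece can be withdrawn en-bloc. Three families:
   **conical** (the cone itself), **flat-based** (cone tip replaced by a
   planar facing cut at the tumor base), **contoured** (tip replaced by a
   curvilinear cut following the tumor's 2D hull).
3. **Minimize bone waste** — Eq. below — with bounded, restarted particle
   swarm optimization over the parameter vector:

       waste % = 100 · B_removed / (B_removed + T_intracortical)

   the healthy-bone share of the removed intracortical volume, counted in
   voxels.

A grid-searched single-plane cut (`best_planar_baseline`) serves as the
planar comparator, and a parametric phantom generator (long-bone shaft +
condylar bulge, sphere/ellipsoid/lobed tumors) provides fully synthetic,
analytically known test scenes — no patient data ships with the package.

## Worked example

Generate a knee-scale phantom (13 mm shaft radius, lobed 8 mm tumor) and
optimize all three cut families:

```sh
resectplan phantom --shaft-radius 13 --tumor-radius 8 --tumor-shape lobed \
    --particles 20 --restarts 3 --seed 7 --out demo_run
```

Output:

```
optimized bone waste (%):
  conical        50.36
  flat           40.48
  contoured      19.29
  planar         89.11  (best single-plane cut)
  improvement conical vs planar: +38.74 pct points
  improvement flat vs planar: +48.63 pct points
  improvement contoured vs planar: +69.82 pct points
```

Reading: the best single plane must amputate a whole cross-section, so 89%
of what it removes is healthy bone. The conical cut narrows that to a
through-column (50%); the flat facing cut stops the column at the tumor
base (40%); the contoured cut additionally conforms sideways to the
tumor's silhouette (19%). The run directory contains the exported cut
surfaces (`rg_*.ply`), profile loops (CSV), the labeled voxel model, a
`report.json` with both waste conventions and all convergence traces, and
`convergence.png`. Every number is re-countable from the stored artifacts:

```sh
resectplan verify demo_run     # rebuilds each RG and re-counts the voxels
```

Equivalent library calls: `phantom.make_scene` / `mesh_model.build_scene` /
`pso_optimizer.optimize_all`; `resectplan plan --bone b.stl --tumor t.stl`
runs the same pipeline on your own segmented meshes, with `--margin-scale`
inflating the tumor uniformly to model a resection margin, and
`resectplan suite` batch-optimizes a whole phantom suite into a CSV.

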