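"""Surface meshes, voxel models and the scene container.

A planning scene holds two watertight triangulated surface meshes (bone and
tumor, shared millimeter frame, as exported by segmentation software) plus a
labeled voxel model: a uniform grid of cube-center points classified as
healthy bone, intracortical tumor (inside both meshes) or extraosseous tumor
(tumor outside the cortical envelope).  Point-in-mesh classification is done
by ray-crossing parity, casting one vertical ray per grid column and counting
surface crossings; degenerate hits (edge/vertex grazes, rays in a triangle
plane) are re-cast along a randomly tilted direction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "LabeledVoxelModel",
    "Scene",
    "MeshError",
    "MeshFormatError",
    "WatertightnessError",
    "DegenerateSceneError",
    "load_mesh",
    "save_mesh",
    "points_in_mesh",
    "voxelize",
    "build_scene",
    "center_on_tumor",
    "expand_margin",
]

#: Distance (mm) within which a point counts as lying *on* a surface or hull
#: boundary; boundary points are classified as inside (conservative toward
#: resection completeness).
BOUNDARY_TOL = 1e-9


class MeshError(ValueError):
    """Base class for surface-mesh validation failures."""


class MeshFormatError(MeshError):
    """File is not a supported surface-mesh format (STL or PLY)."""


class WatertightnessError(MeshError):
    """Mesh has open edges after cleanup and cannot bound a volume."""

    def __init__(self, label: str, open_edge_count: int):
        self.open_edge_count = open_edge_count
        super().__init__(
            f"{label} mesh is not watertight: {open_edge_count} open edge(s); "
            "a closed surface is required for inside/outside classification"
        )


class DegenerateSceneError(ValueError):
    """Voxelization produced an empty healthy-bone or tumor point set."""


@dataclasses.dataclass
class SurfaceMesh:
    """Watertight triangulated surface in millimeters.

    Parameters
    ----------
    vertices : (n, 3) float array, mm.
    faces : (m, 3) int array of triangle vertex indices, outward-oriented.
    label : ``"bone"`` or ``"tumor"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.shape[0] < 4:
            raise MeshError("a closed surface needs at least 4 vertices")

    @property
    def centroid(self) -> np.ndarray:
        """Mean of the mesh vertices (the tumor centering reference)."""
        return self.vertices.mean(axis=0)

    @property
    def volume(self) -> float:
        """Enclosed volume in mm^3 (divergence theorem)."""
        return float(self.as_trimesh().volume)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def translated(self, offset) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(offset, float),
                           self.faces.copy(), self.label)


@dataclasses.dataclass
class LabeledVoxelModel:
    """Uniform cube-center grid labeled healthy bone / tumor.

    All centers lie on the lattice ``origin_offset + pitch * (k + 1/2)`` for
    integer k per axis, where ``origin_offset`` is the minimum corner of the
    joint bounding box at voxelization time plus any rigid translations
    applied since.  Voxel volume is ``pitch**3`` mm^3.
    """

    pitch: float
    origin_offset: np.ndarray
    healthy_bone_points: np.ndarray
    intracortical_tumor_points: np.ndarray
    extraosseous_tumor_points: np.ndarray

    @property
    def voxel_volume(self) -> float:
        return float(self.pitch) ** 3

    @property
    def tumor_points(self) -> np.ndarray:
        """All tumor voxel centers, intracortical then extraosseous."""
        return np.vstack(
            [self.intracortical_tumor_points, self.extraosseous_tumor_points]
        )

    def counts(self) -> dict:
        return {
            "healthy_bone": int(len(self.healthy_bone_points)),
            "intracortical_tumor": int(len(self.intracortical_tumor_points)),
            "extraosseous_tumor": int(len(self.extraosseous_tumor_points)),
        }

    def translated(self, offset) -> "LabeledVoxelModel":
        off = np.asarray(offset, float)
        return LabeledVoxelModel(
            self.pitch,
            self.origin_offset + off,
            self.healthy_bone_points + off,
            self.intracortical_tumor_points + off,
            self.extraosseous_tumor_points + off,
        )

    # -- serialization -------------------------------------------------
    _LABELS = ("healthy_bone", "intracortical_tumor", "extraosseous_tumor")

    def to_csv(self, path):
        """Write ``x,y,z,label`` rows for inspection."""
        with open(path, "w") as fh:
            fh.write("x,y,z,label\n")
            for name in self._LABELS:
                pts = getattr(self, name + "_points")
                for x, y, z in pts:
                    fh.write(f"{x:.6f},{y:.6f},{z:.6f},{name}\n")

    def to_npz(self, path):
        """Write a compressed columnar archive of centers and labels."""
        np.savez_compressed(
            path,
            pitch=self.pitch,
            origin_offset=self.origin_offset,
            **{n: getattr(self, n + "_points") for n in self._LABELS},
        )

    @classmethod
    def from_npz(cls, path) -> "LabeledVoxelModel":
        with np.load(path) as data:
            return cls(
                float(data["pitch"]),
                np.asarray(data["origin_offset"], float),
                *[np.asarray(data[n], float) for n in cls._LABELS],
            )


@dataclasses.dataclass
class Scene:
    """Bone mesh + tumor mesh + labeled voxel model in one frame.

    After :func:`center_on_tumor` the tumor-mesh centroid is at the origin.
    ``original_tumor_mesh`` retains the pre-margin-expansion tumor when
    :func:`expand_margin` has been applied, for reporting.
    """

    bone_mesh: SurfaceMesh
    tumor_mesh: SurfaceMesh
    voxels: LabeledVoxelModel | None = None
    original_tumor_mesh: SurfaceMesh | None = None

    @property
    def pitch(self) -> float:
        if self.voxels is None:
            raise ValueError("scene has not been voxelized")
        return self.voxels.pitch


# ---------------------------------------------------------------------------
# mesh I/O


def load_mesh(path, label: str) -> SurfaceMesh:
    """Load and validate an STL (binary or ASCII) or PLY surface mesh.

    The mesh is cleaned (duplicate vertices merged, zero-area and duplicate
    faces dropped), its face normals made consistently outward, and
    watertightness enforced.

    Raises
    ------
    MeshFormatError
        If the file suffix is not ``.stl`` or ``.ply``.
    WatertightnessError
        If open edges remain after cleanup (the count is reported).
    """
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise MeshFormatError(
            f"unsupported mesh format {path.suffix!r}; expected .stl or .ply"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    tm = trimesh.load(str(path), force="mesh")
    return _clean(tm, label)


def _clean(tm: trimesh.Trimesh, label: str) -> SurfaceMesh:
    tm = trimesh.Trimesh(vertices=tm.vertices, faces=tm.faces, process=True)
    tm.update_faces(tm.nondegenerate_faces())
    tm.update_faces(tm.unique_faces())
    tm.remove_unreferenced_vertices()
    if not tm.is_watertight:
        # edges referenced by a number of faces != 2
        edges = trimesh.grouping.group_rows(tm.edges_sorted, require_count=1)
        raise WatertightnessError(label, int(len(edges)))
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), label)


def save_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a mesh as STL or PLY (chosen by suffix)."""
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise MeshFormatError(f"unsupported export format {path.suffix!r}")
    mesh.as_trimesh().export(str(path))


# ---------------------------------------------------------------------------
# ray-parity point classification


def points_in_mesh(points, mesh: SurfaceMesh, tol: float = BOUNDARY_TOL,
                   rng=None) -> np.ndarray:
    """Classify points as inside a watertight mesh by ray-crossing parity.

    One vertical (+z) ray is cast from each query point and surface
    crossings above the point are counted; odd parity means inside.  A point
    within ``tol`` mm of the surface counts as inside.  Rays that graze a
    triangle edge/vertex, or lie in the plane of a near-vertical triangle,
    are re-cast along a small random tilt until the hit is unambiguous.

    Returns a boolean mask of shape ``(len(points),)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    verts = mesh.vertices
    tris = verts[mesh.faces]  # (m, 3, 3)
    n = len(pts)
    if n == 0:
        return np.zeros(0, dtype=bool)

    scale = max(np.ptp(verts, axis=0).max(), 1.0)
    edge_eps = 1e-10  # barycentric slack marking a graze as ambiguous

    counts = np.zeros(n, dtype=np.int64)
    on_surface = np.zeros(n, dtype=bool)
    uncertain = np.zeros(n, dtype=bool)

    order = np.argsort(pts[:, 0], kind="stable")
    xs = pts[order, 0]

    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    # 2D projected edge vectors and triangle bounding boxes
    det = ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
           - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))
    lo = tris[:, :, :2].min(axis=1)
    hi = tris[:, :, :2].max(axis=1)
    vertical = np.abs(det) < 1e-12 * scale * scale

    for t in range(len(tris)):
        i0 = np.searchsorted(xs, lo[t, 0] - tol, side="left")
        i1 = np.searchsorted(xs, hi[t, 0] + tol, side="right")
        if i0 >= i1:
            continue
        cand = order[i0:i1]
        cand = cand[(pts[cand, 1] >= lo[t, 1] - tol)
                    & (pts[cand, 1] <= hi[t, 1] + tol)]
        if len(cand) == 0:
            continue
        if vertical[t]:
            # ray parallel to the triangle plane in projection: ambiguous
            uncertain[cand] = True
            continue
        px = pts[cand, 0] - a[t, 0]
        py = pts[cand, 1] - a[t, 1]
        inv = 1.0 / det[t]
        u = ((c[t, 1] - a[t, 1]) * px - (c[t, 0] - a[t, 0]) * py) * inv
        v = (-(b[t, 1] - a[t, 1]) * px + (b[t, 0] - a[t, 0]) * py) * inv
        w = 1.0 - u - v
        bmin = np.minimum(np.minimum(u, v), w)
        hit = bmin > edge_eps
        graze = np.abs(bmin) <= edge_eps
        touch = hit | graze
        if not touch.any():
            continue
        zhit = (w[touch] * a[t, 2] + u[touch] * b[t, 2]
                + v[touch] * c[t, 2])
        near = np.abs(zhit - pts[cand[touch], 2]) <= tol
        on_surface[cand[touch][near]] = True
        uncertain[cand[graze]] = True
        if hit.any():
            hc = cand[hit]
            zh = w[hit] * a[t, 2] + u[hit] * b[t, 2] + v[hit] * c[t, 2]
            counts[hc] += zh - pts[hc, 2] > tol

    inside = (counts % 2 == 1) | on_surface

    bad = np.flatnonzero(uncertain & ~on_surface)
    if len(bad):
        rng = np.random.default_rng(0) if rng is None else rng
        inside[bad] = _recast(pts[bad], tris, tol, rng) | on_surface[bad]
    return inside


def _recast(pts, tris, tol, rng, max_tries: int = 8) -> np.ndarray:
    """Moller-Trumbore parity along a random tilted direction, per point."""
    out = np.zeros(len(pts), dtype=bool)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    for i, p in enumerate(pts):
        for _ in range(max_tries):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pvec = np.cross(d, e2)
            det = np.einsum("ij,ij->i", e1, pvec)
            ok = np.abs(det) > 1e-14
            tv = p - tris[ok, 0]
            inv = 1.0 / det[ok]
            u = np.einsum("ij,ij->i", tv, pvec[ok]) * inv
            qvec = np.cross(tv, e1[ok])
            v = (qvec @ d) * inv
            thit = np.einsum("ij,ij->i", e2[ok], qvec) * inv
            w = 1.0 - u - v
            bmin = np.minimum(np.minimum(u, v), w)
            if np.any((bmin >= -1e-9) & (np.abs(thit) <= tol)):
                out[i] = True  # point lies on the surface itself
                break
            if np.any((np.abs(bmin) <= 1e-10) & (thit > tol)):
                continue  # grazed an edge ahead: new direction
            out[i] = ((bmin > 1e-10) & (thit > tol)).sum() % 2 == 1
            break
        else:  # pragma: no cover - pathological mesh
            out[i] = False
    return out


# ---------------------------------------------------------------------------
# voxelization and scene assembly


def voxelize(bone: SurfaceMesh, tumor: SurfaceMesh,
             pitch: float = 2.0) -> LabeledVoxelModel:
    """Build the labeled cube-center grid spanning both meshes.

    The grid covers the joint axis-aligned bounding box with the minimum
    corner on a lattice corner, centers at ``min + pitch * (k + 1/2)``.
    Each center is classified against both meshes by ray parity; centers
    outside both are discarded, bone centers inside the tumor become
    intracortical tumor, tumor centers outside the bone are extraosseous.

    Raises
    ------
    DegenerateSceneError
        If no healthy-bone centers or no tumor centers remain.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    lo = np.minimum(bone.vertices.min(axis=0), tumor.vertices.min(axis=0))
    hi = np.maximum(bone.vertices.max(axis=0), tumor.vertices.max(axis=0))
    axes = [np.arange(lo[i] + pitch / 2.0, hi[i], pitch) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    in_bone = points_in_mesh(centers, bone)
    # only centers inside the tumor AABB can be inside the tumor
    tlo = tumor.vertices.min(axis=0) - BOUNDARY_TOL
    thi = tumor.vertices.max(axis=0) + BOUNDARY_TOL
    near = np.all((centers >= tlo) & (centers <= thi), axis=1)
    in_tumor = np.zeros(len(centers), dtype=bool)
    in_tumor[near] = points_in_mesh(centers[near], tumor)

    healthy = centers[in_bone & ~in_tumor]
    intracortical = centers[in_bone & in_tumor]
    extraosseous = centers[in_tumor & ~in_bone]
    if len(healthy) == 0:
        raise DegenerateSceneError("no healthy-bone voxel centers")
    if len(intracortical) + len(extraosseous) == 0:
        raise DegenerateSceneError("no tumor voxel centers")
    return LabeledVoxelModel(float(pitch), lo.copy(), healthy,
                             intracortical, extraosseous)


def center_on_tumor(scene: Scene) -> Scene:
    """Translate the whole scene so the tumor-mesh centroid is the origin.

    A rigid translation by minus the tumor vertex mean applied to both
    meshes and every voxel point set; idempotent.
    """
    if scene.voxels is None:
        raise ValueError("voxelize the scene before centering")
    offset = -scene.tumor_mesh.centroid
    return Scene(
        scene.bone_mesh.translated(offset),
        scene.tumor_mesh.translated(offset),
        scene.voxels.translated(offset),
        (scene.original_tumor_mesh.translated(offset)
         if scene.original_tumor_mesh is not None else None),
    )


def expand_margin(tumor: SurfaceMesh, margin_scale: float) -> SurfaceMesh:
    """Uniformly scale the tumor about its centroid to add a safety margin.

    The planning tumor is grown by ``margin_scale`` (>= 1) so the resection
    encloses a cuff of healthy tissue; the caller keeps the original mesh
    for reporting.
    """
    if margin_scale < 1.0:
        raise ValueError("margin_scale must be >= 1")
    c = tumor.centroid
    return SurfaceMesh(c + margin_scale * (tumor.vertices - c),
                       tumor.faces.copy(), tumor.label)


def build_scene(bone: SurfaceMesh, tumor: SurfaceMesh, pitch: float = 2.0,
                margin_scale: float = 1.0) -> Scene:
    """Voxelize, optionally expand the tumor margin, and center on the tumor."""
    original = None
    if margin_scale != 1.0:
        original = tumor
        tumor = expand_margin(tumor, margin_scale)
    voxels = voxelize(bone, tumor, pitch)
    scene = Scene(bone, tumor, voxels, original)
    return center_on_tumor(scene)
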