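"""Convex-hull resection geometries and the bone-waste objective.

A resection geometry (RG) is the cut surface separating removed from
retained tissue.  All three RGs start from the same construction: rotate the
scene about the base z, y and x axes, translate it in the rotated (local)
frame so the focal point FP sits at the local origin below the tumor, and
form the quasi-conical surface spanned by rays from FP through the convex
hull of the tumor surface vertices.  The rays are carried past the tumor
and out through the far cortex — the resected piece must be withdrawable
en-bloc, so the cut passes through the whole bone and every healthy voxel
inside the cone counts as collaterally removed.

* conical   — the extended cone itself.
* flat      — the cone tip is removed by a planar facing cut at the lowest
              tumor z in the local frame (healthy bone strictly below that
              plane is retained).
* contoured — after one extra rotation about the local z axis, the tip is
              instead removed by a curvilinear cut: only bone whose (x, z)
              projection falls inside the 2D convex hull of the projected
              tumor is removed.

Bone waste is the fraction of the removed volume that is healthy bone:
``100 * removed / (removed + intracortical)`` where ``intracortical`` is the
tumor volume inside the cortical envelope.  Counting is purely voxel-based.

Cone membership is evaluated in a form that stays well-conditioned for focal
points up to 200 m below the tumor (the quasi-cylindrical limit): a point p
lies in the cone from FP over ``conv(T')`` iff the ray from FP through p
meets ``conv(T')`` at some parameter t > 0 (t >= 1 restricts to the hull
``conv(T' ∪ {FP})`` itself), which reduces to a per-point interval
intersection over the facets of ``conv(T')`` alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .mesh_model import BOUNDARY_TOL, Scene

__all__ = [
    "RGParams",
    "LocalFrame",
    "ResectionGeometry",
    "WasteResult",
    "DegenerateHullError",
    "InfeasiblePlaneError",
    "ParameterError",
    "RG_TYPES",
    "rotation_zyx",
    "local_translation_bounds",
    "sample_params",
    "to_local",
    "point_in_hull_3d",
    "build_rg",
    "build_conical",
    "build_flat_based",
    "build_contoured",
    "bone_waste",
    "extend_profile",
    "planar_baseline",
    "best_planar_baseline",
]

RG_TYPES = ("conical", "flat", "contoured")

#: Translation bound along the local z axis: numerically "infinitely far",
#: giving quasi-cylindrical resections.
T_Z_LOWER_BOUND = -200_000.0


class DegenerateHullError(ValueError):
    """Hull generators are affinely dependent (coplanar/collinear tumor)."""


class InfeasiblePlaneError(ValueError):
    """A baseline cutting plane intersects the tumor."""


class ParameterError(ValueError):
    """A resection parameter lies outside its bounds."""


# ---------------------------------------------------------------------------
# parameters and frames


@dataclasses.dataclass
class RGParams:
    """Resection parameter vector.

    ``theta_z/theta_y/theta_x`` are extrinsic rotations (degrees, applied in
    z, y, x order) of the scene about the fixed base axes; ``t_x/t_y/t_z``
    translate the rotated scene so the focal point is the local origin
    (bounds: the rotated tumor x/y extents and ``[-200000, min(T'_z)]``);
    ``phi_z`` (degrees, +/-90) is the extra local-z rotation used only by the
    contoured RG.
    """

    theta_z: float
    theta_y: float
    theta_x: float
    t_x: float
    t_y: float
    t_z: float
    phi_z: float | None = None
    rg_type: str = "conical"

    def __post_init__(self):
        if self.rg_type not in RG_TYPES:
            raise ParameterError(f"unknown rg_type {self.rg_type!r}")
        if (self.phi_z is not None) != (self.rg_type == "contoured"):
            raise ParameterError("phi_z is present iff rg_type='contoured'")

    @property
    def n_params(self) -> int:
        return 7 if self.rg_type == "contoured" else 6

    def to_vector(self) -> np.ndarray:
        v = [self.theta_z, self.theta_y, self.theta_x,
             self.t_x, self.t_y, self.t_z]
        if self.rg_type == "contoured":
            v.append(self.phi_z)
        return np.asarray(v, dtype=float)

    @classmethod
    def from_vector(cls, vec, rg_type: str) -> "RGParams":
        vec = np.asarray(vec, dtype=float)
        need = 7 if rg_type == "contoured" else 6
        if vec.shape != (need,):
            raise ParameterError(
                f"{rg_type} RG needs {need} parameters, got {vec.shape}")
        phi = float(vec[6]) if rg_type == "contoured" else None
        return cls(*[float(x) for x in vec[:6]], phi_z=phi, rg_type=rg_type)

    def validate(self, scene: Scene, tol: float = 1e-9) -> None:
        """Check every value against its bound in the current local frame."""
        for name in ("theta_z", "theta_y", "theta_x"):
            if abs(getattr(self, name)) > 180.0 + tol:
                raise ParameterError(f"{name} outside +/-180 deg")
        if self.phi_z is not None and abs(self.phi_z) > 90.0 + tol:
            raise ParameterError("phi_z outside +/-90 deg")
        R = rotation_zyx(self.theta_z, self.theta_y, self.theta_x)
        (xlo, xhi), (ylo, yhi), zhi = local_translation_bounds(
            R, scene.tumor_mesh.vertices)
        if not (xlo - tol <= self.t_x <= xhi + tol):
            raise ParameterError("t_x outside rotated tumor x extent")
        if not (ylo - tol <= self.t_y <= yhi + tol):
            raise ParameterError("t_y outside rotated tumor y extent")
        if not (T_Z_LOWER_BOUND - tol <= self.t_z <= zhi + tol):
            raise ParameterError("t_z outside [-200000, min(T'_z)]")


def _rot(axis: int, deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


def rotation_zyx(theta_z: float, theta_y: float, theta_x: float) -> np.ndarray:
    """Extrinsic rotations about the fixed base axes, applied z then y then x."""
    return _rot(0, theta_x) @ _rot(1, theta_y) @ _rot(2, theta_z)


def local_translation_bounds(R: np.ndarray, tumor_vertices: np.ndarray):
    """Translation bounds in the rotated frame: tumor x/y extents, min z."""
    t = tumor_vertices @ R.T
    return ((float(t[:, 0].min()), float(t[:, 0].max())),
            (float(t[:, 1].min()), float(t[:, 1].max())),
            float(t[:, 2].min()))


@dataclasses.dataclass
class LocalFrame:
    """Rigid map between the base frame and the RG's local frame.

    ``local = Rz(phi_z) @ (R @ base - t)`` with the focal point at the local
    origin; ``R`` is the composed base rotation, ``t = (t_x, t_y, t_z)``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    local_z_rotation: float | None = None

    def __post_init__(self):
        R = self.rotation
        if not (np.allclose(R @ R.T, np.eye(3), atol=1e-12)
                and abs(np.linalg.det(R) - 1.0) < 1e-12):
            raise ValueError("rotation must be orthonormal, det +1")
        self._phi = (np.eye(3) if self.local_z_rotation is None
                     else _rot(2, self.local_z_rotation))

    @classmethod
    def from_params(cls, params: RGParams) -> "LocalFrame":
        return cls(rotation_zyx(params.theta_z, params.theta_y,
                                params.theta_x),
                   np.array([params.t_x, params.t_y, params.t_z]),
                   params.phi_z)

    def to_local_pts(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) @ self.rotation.T
                - self.translation) @ self._phi.T

    def to_base_pts(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) @ self._phi
                + self.translation) @ self.rotation

    @property
    def focal_point_base(self) -> np.ndarray:
        """The local origin expressed in base coordinates."""
        return self.rotation.T @ self.translation


def to_local(scene: Scene, params: RGParams, validate: bool = True) -> dict:
    """Express the scene's point sets in the RG's local frame.

    Returns a dict with ``tumor_vertices``, ``bone_vertices``,
    ``healthy_bone``, ``intracortical`` arrays and the ``frame``.
    """
    if validate:
        params.validate(scene)
    frame = LocalFrame.from_params(params)
    vox = scene.voxels
    return {
        "frame": frame,
        "tumor_vertices": frame.to_local_pts(scene.tumor_mesh.vertices),
        "bone_vertices": frame.to_local_pts(scene.bone_mesh.vertices),
        "healthy_bone": frame.to_local_pts(vox.healthy_bone_points),
        "intracortical": frame.to_local_pts(vox.intracortical_tumor_points),
    }


# ---------------------------------------------------------------------------
# hull membership


def point_in_hull_3d(points, hull_generators, tol: float = BOUNDARY_TOL
                     ) -> np.ndarray:
    """Half-space membership test against the hull of a generator set.

    True where the point satisfies every facet inequality of
    ``conv(hull_generators)`` within ``tol`` (boundary counts as inside).
    Works for 2D or 3D generator sets.

    Raises
    ------
    DegenerateHullError
        If the generators are affinely dependent.
    """
    gen = np.asarray(hull_generators, float)
    try:
        hull = ConvexHull(gen)
    except QhullError as exc:
        raise DegenerateHullError(
            f"degenerate hull generators: {exc}") from exc
    pts = np.atleast_2d(np.asarray(points, float))
    eqs = hull.equations  # unit normal, offset with n.x + b <= 0 inside
    slack = pts @ eqs[:, :-1].T + eqs[:, -1]
    return np.all(slack <= tol, axis=1)


def _tumor_hull_equations(tumor_local: np.ndarray) -> np.ndarray:
    try:
        return ConvexHull(tumor_local).equations
    except QhullError as exc:
        raise DegenerateHullError(
            f"tumor hull is degenerate: {exc}") from exc


def _cone_membership(points: np.ndarray, eqs: np.ndarray,
                     t_min: float = 1.0,
                     tol: float = BOUNDARY_TOL) -> np.ndarray:
    """Membership in the cone from the local origin over ``conv(T')``.

    With the focal point at the origin, ``p ∈ conv(T' ∪ {0})`` iff the ray
    ``t p`` meets ``conv(T')`` for some ``t >= 1``; with ``t_min → 0`` the
    same test gives the *infinite* cone.  Each hull facet ``n.x + b <= 0``
    yields one linear constraint ``t (n.p) <= -b``; feasibility of the
    interval intersection is checked per point, fully vectorized, using only
    the (well-conditioned, tumor-scale) facets of ``conv(T')``.
    """
    pts = np.atleast_2d(points)
    normals, offs = eqs[:, :-1], eqs[:, -1]
    S = pts @ normals.T                    # (n, m)
    Rb = -offs[None, :] + tol              # boundary-inclusive slack
    nrm = np.linalg.norm(pts, axis=1)
    eps = 1e-13 * np.maximum(nrm, 1.0)[:, None]
    pos = S > eps
    neg = S < -eps
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = Rb / S
    t_hi = np.where(pos, ratio, np.inf).min(axis=1)
    t_lo = np.where(neg, ratio, -np.inf).max(axis=1)
    infeasible = ((~pos & ~neg) & (Rb < 0)).any(axis=1)
    lo = np.maximum(t_lo, t_min)
    inside = ~infeasible & (t_hi >= lo * (1 - 1e-12) - 1e-15)
    inside |= nrm <= tol  # the apex itself
    return inside


def _cone_prefilter(points: np.ndarray, T: np.ndarray,
                    tol: float = BOUNDARY_TOL) -> np.ndarray:
    """Cheap superset of the infinite cone over ``conv(T')`` from the origin.

    With c the tumor vertex centroid, R its circumscribing radius and
    d = |c|, every cone point ``p = t q`` (q in ball(c, R), t > 0) has
    ``p . c > 0`` and distance to the apex-centroid line at most
    ``t R <= R |p| / (d - R)``.  Points violating either bound cannot be in
    the cone and are skipped by the exact facet test.  Degenerate when the
    apex is inside the circumscribing ball (everything kept).
    """
    c = T.mean(axis=0)
    R = float(np.linalg.norm(T - c, axis=1).max())
    d = float(np.linalg.norm(c))
    if d <= R + tol:
        return np.ones(len(points), dtype=bool)
    proj = points @ (c / d)
    norm2 = np.einsum("ij,ij->i", points, points)
    perp2 = np.maximum(norm2 - proj * proj, 0.0)
    bound = R * np.sqrt(norm2) / (d - R) + tol
    return (proj >= -tol) & (perp2 <= bound * bound)


# ---------------------------------------------------------------------------
# resection geometries


@dataclasses.dataclass
class WasteResult:
    """Voxel-counted bone waste for one realized resection."""

    bone_waste_pct: float
    removed_count: int
    intracortical_count: int
    extraosseous_count: int = 0

    @property
    def bone_waste_pct_whole_tumor(self) -> float:
        """Alternative convention: whole tumor volume in the denominator."""
        denom = (self.removed_count + self.intracortical_count
                 + self.extraosseous_count)
        return 100.0 * self.removed_count / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "bone_waste_pct": self.bone_waste_pct,
            "bone_waste_pct_whole_tumor": self.bone_waste_pct_whole_tumor,
            "removed_count": self.removed_count,
            "intracortical_count": self.intracortical_count,
            "extraosseous_count": self.extraosseous_count,
        }


def bone_waste(removed_count: int, intracortical_count: int) -> float:
    """Collaterally resected healthy bone as a percentage of the resection.

    ``100 * removed / (removed + intracortical)``; the denominator is the
    total intracortical resection volume, so the value is < 100 whenever any
    tumor is removed and 0 for a perfectly conformal cut.
    """
    if intracortical_count <= 0:
        raise DegenerateSceneWasteError(
            "bone waste undefined: no intracortical tumor volume")
    return 100.0 * removed_count / (removed_count + intracortical_count)


class DegenerateSceneWasteError(ValueError):
    """Bone waste requested for a scene without intracortical tumor."""


@dataclasses.dataclass
class ResectionGeometry:
    """A realized cut: focal point, profile loops and removed voxel set.

    ``profile_3d`` holds the cone profile points (base frame, ordered by
    azimuth about the local z axis); ``facing_profile`` the planar or
    curvilinear facing-cut loop (None for conical).  ``removed_indices``
    index into ``scene.voxels.healthy_bone_points``.
    """

    rg_type: str
    params: RGParams
    frame: LocalFrame
    focal_point: np.ndarray
    profile_3d: np.ndarray
    facing_profile: np.ndarray | None
    removed_indices: np.ndarray
    pitch: float
    complete: bool
    extended: bool = False

    @property
    def removed_volume(self) -> float:
        return len(self.removed_indices) * self.pitch ** 3

    def to_mesh(self):
        """Triangulate the cut surface (cone panels + facing cut) for export."""
        import trimesh

        loop = self.profile_3d
        k = len(loop)
        if self.facing_profile is None or len(self.facing_profile) < 3:
            verts = np.vstack([self.focal_point[None, :], loop])
            faces = [[0, 1 + i, 1 + (i + 1) % k] for i in range(k)]
        else:
            fp = self.facing_profile
            m = len(fp)
            verts = np.vstack([loop, fp, fp.mean(axis=0)[None, :]])
            faces = []
            for i in range(k):  # side panels between profile and facing loop
                j = int(round(i * m / k)) % m
                j2 = int(round((i + 1) * m / k)) % m
                faces.append([i, (i + 1) % k, k + j])
                if j2 != j:
                    faces.append([(i + 1) % k, k + j2, k + j])
            for j in range(m):  # facing-cut fan
                faces.append([k + j, k + (j + 1) % m, k + m])
        return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                               process=False)


def _order_by_azimuth(local_pts: np.ndarray) -> np.ndarray:
    ang = np.arctan2(local_pts[:, 1], local_pts[:, 0])
    return np.argsort(ang, kind="stable")


def build_rg(scene: Scene, params: RGParams, profile: bool = True,
             validate: bool = True):
    """Build the resection geometry named by ``params.rg_type``.

    Returns ``(ResectionGeometry, WasteResult)``.  The removed set is the
    healthy bone inside the focal cone carried through the whole bone
    (truncating the cone just beyond the farthest contained bone point
    yields the identical count), intersected with the family's facing cut.
    Every intracortical tumor voxel is inside the removed region by
    construction; the realized flag is stored as ``rg.complete``.
    ``profile=False`` skips construction of the exportable profile loops
    (the optimizer only needs the voxel counts).
    """
    local = to_local(scene, params, validate=validate)
    frame = local["frame"]
    T = local["tumor_vertices"]
    B = local["healthy_bone"]
    I = local["intracortical"]
    try:
        hull3d = ConvexHull(T)
    except QhullError as exc:
        raise DegenerateHullError(
            f"tumor hull is degenerate: {exc}") from exc
    eqs = hull3d.equations
    facing_local = None

    # cheap exact-superset cuts first, the facet-interval cone test last
    candidate = _cone_prefilter(B, T)
    tumor_in = np.ones(len(I), dtype=bool)

    if params.rg_type == "flat":
        zmin = float(T[:, 2].min())
        candidate &= B[:, 2] > zmin
        tumor_in &= I[:, 2] > zmin
        if profile:
            facing_local = _cone_section(T, hull3d, zmin)
    elif params.rg_type == "contoured":
        xz = T[:, [0, 2]]
        try:
            hull2d = ConvexHull(xz)
        except QhullError as exc:
            raise DegenerateHullError(
                f"tumor xz projection is degenerate: {exc}") from exc
        e2 = hull2d.equations
        candidate &= np.all(B[:, [0, 2]] @ e2[:, :-1].T + e2[:, -1]
                            <= BOUNDARY_TOL, axis=1)
        tumor_in &= np.all(I[:, [0, 2]] @ e2[:, :-1].T + e2[:, -1]
                           <= BOUNDARY_TOL, axis=1)
        if profile:
            loop2d = xz[hull2d.vertices]  # counter-clockwise
            facing_local = np.column_stack(
                [loop2d[:, 0], np.zeros(len(loop2d)), loop2d[:, 1]])

    # the cut is carried through the cortex (the piece must be removable
    # en-bloc), so healthy bone anywhere inside the cone counts as removed
    removed = np.zeros(len(B), dtype=bool)
    removed[candidate] = _cone_membership(B[candidate], eqs, t_min=1e-12)
    if len(I):
        tumor_in &= _cone_membership(I, eqs, t_min=1e-12)

    if profile:
        hull_pts = T[np.unique(hull3d.vertices)]
        order = _order_by_azimuth(hull_pts)
        profile_pts = frame.to_base_pts(hull_pts[order])
        facing = (frame.to_base_pts(facing_local)
                  if facing_local is not None else None)
    else:
        profile_pts = np.zeros((0, 3))
        facing = None

    idx = np.flatnonzero(removed)
    waste = WasteResult(
        bone_waste_pct=bone_waste(len(idx), len(I)),
        removed_count=int(len(idx)),
        intracortical_count=int(len(I)),
        extraosseous_count=int(
            len(scene.voxels.extraosseous_tumor_points)),
    )
    rg = ResectionGeometry(
        rg_type=params.rg_type,
        params=params,
        frame=frame,
        focal_point=frame.focal_point_base,
        profile_3d=profile_pts,
        facing_profile=facing,
        removed_indices=idx,
        pitch=scene.pitch,
        complete=bool(tumor_in.all()) if len(I) else True,
    )
    return rg, waste


def _cone_section(T: np.ndarray, hull3d: ConvexHull, z: float) -> np.ndarray:
    """Cross-section loop of the cone ``conv(T' ∪ {0})`` at height z."""
    if z <= BOUNDARY_TOL:
        return np.zeros((0, 3))
    hull_pts = T[np.unique(hull3d.vertices)]
    ok = hull_pts[:, 2] > BOUNDARY_TOL
    sec = hull_pts[ok] * (z / hull_pts[ok, 2])[:, None]
    return sec[_order_by_azimuth(sec)]


def build_conical(scene: Scene, params: RGParams):
    """Conical hull RG: ``conv(tumor ∪ focal point)``."""
    if params.rg_type != "conical":
        raise ParameterError("params.rg_type must be 'conical'")
    return build_rg(scene, params)


def build_flat_based(scene: Scene, params: RGParams):
    """Flat-based hull RG: cone tip replaced by the planar facing cut."""
    if params.rg_type != "flat":
        raise ParameterError("params.rg_type must be 'flat'")
    return build_rg(scene, params)


def build_contoured(scene: Scene, params: RGParams):
    """Contoured hull RG: cone tip replaced by the curvilinear 2D-hull cut."""
    if params.rg_type != "contoured":
        raise ParameterError("params.rg_type must be 'contoured'")
    return build_rg(scene, params)


def extend_profile(rg: ResectionGeometry, scene: Scene,
                   clearance: float = 5.0) -> ResectionGeometry:
    """Lengthen the profile rays so the exported cut clears the anatomy.

    Each focal-point-to-profile-vertex ray is extended to the distance of
    the farthest bone or tumor point lying inside the infinite cone, plus
    ``clearance`` mm, so the exported surface clears the cortex and the
    piece can be withdrawn en-bloc.  Voxel counting (and hence waste) is
    unaffected: the count already includes everything inside the cone up to
    the farthest contained bone point.
    """
    frame = rg.frame
    eqs = _tumor_hull_equations(
        frame.to_local_pts(scene.tumor_mesh.vertices))
    cloud = np.vstack([scene.voxels.healthy_bone_points,
                       scene.voxels.intracortical_tumor_points,
                       scene.tumor_mesh.vertices])
    local = frame.to_local_pts(cloud)
    in_cone = _cone_membership(local, eqs, t_min=1e-12)
    dist = np.linalg.norm(local[in_cone], axis=1)
    reach = float(dist.max()) + clearance if in_cone.any() else clearance

    prof_local = frame.to_local_pts(rg.profile_3d)
    norms = np.linalg.norm(prof_local, axis=1)
    norms[norms < 1e-12] = 1.0
    factor = np.maximum(reach / norms, 1.0)
    extended_local = prof_local * factor[:, None]
    return dataclasses.replace(
        rg, profile_3d=frame.to_base_pts(extended_local), extended=True)


def sample_params(scene: Scene, rg_type: str, rng) -> RGParams:
    """Draw one uniformly random in-bounds parameter vector.

    Rotations are uniform over +/-180 deg (phi_z over +/-90); translations
    are uniform over the bounds induced by the drawn rotation, with t_z
    uniform down to the quasi-cylindrical limit.
    """
    th = rng.uniform(-180.0, 180.0, size=3)
    R = rotation_zyx(*th)
    (xlo, xhi), (ylo, yhi), zhi = local_translation_bounds(
        R, scene.tumor_mesh.vertices)
    vec = [th[0], th[1], th[2],
           rng.uniform(xlo, xhi), rng.uniform(ylo, yhi),
           rng.uniform(T_Z_LOWER_BOUND, zhi)]
    if rg_type == "contoured":
        vec.append(rng.uniform(-90.0, 90.0))
    return RGParams.from_vector(vec, rg_type)


# ---------------------------------------------------------------------------
# planar comparator


def planar_baseline(scene: Scene, normal, offset: float) -> WasteResult:
    """Waste of a single planar cut: remove everything with ``n.x > offset``.

    The plane must strictly separate the tumor (voxel centers and mesh
    vertices) into the removed half-space.
    """
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    vox = scene.voxels
    tumor_pts = np.vstack([vox.tumor_points, scene.tumor_mesh.vertices])
    if not np.all(tumor_pts @ n > offset):
        raise InfeasiblePlaneError(
            "cutting plane intersects the tumor; no en-bloc planar resection")
    removed = int(np.count_nonzero(vox.healthy_bone_points @ n > offset))
    n_intra = len(vox.intracortical_tumor_points)
    return WasteResult(bone_waste(removed, n_intra), removed, n_intra,
                       len(vox.extraosseous_tumor_points))


def best_planar_baseline(scene: Scene, n_directions: int = 200,
                         eps: float = 1e-6):
    """Grid search the best feasible single-plane resection.

    Directions are a Fibonacci covering of the sphere; for a fixed normal
    the optimal offset is analytic (just below the tumor's minimal support
    value), so no offset grid is needed.  Returns ``(WasteResult, normal,
    offset)`` for the minimum-waste plane.
    """
    i = np.arange(n_directions)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_directions
    r = np.sqrt(np.maximum(1 - z * z, 0.0))
    phi = 2 * np.pi * i / golden
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    vox = scene.voxels
    tumor_pts = np.vstack([vox.tumor_points, scene.tumor_mesh.vertices])
    healthy = vox.healthy_bone_points
    n_intra = len(vox.intracortical_tumor_points)

    support = tumor_pts @ dirs.T            # (n_pts, n_dirs)
    offsets = support.min(axis=0) - eps
    counts = (healthy @ dirs.T > offsets).sum(axis=0)
    k = int(np.argmin(counts))
    waste = WasteResult(bone_waste(int(counts[k]), n_intra),
                        int(counts[k]), n_intra,
                        len(vox.extraosseous_tumor_points))
    return waste, dirs[k], float(offsets[k])
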