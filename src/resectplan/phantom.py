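"""Parametric synthetic bone + tumor scenes with known analytic geometry.

The phantoms stand in for segmented patient anatomy: a long-bone-like shaft
with a condylar bulge at one end, and an intersecting tumor (sphere,
ellipsoid, or a lobed star-shaped solid), both as watertight triangulated
surface meshes in millimeters.  The bone is a generalized surface of
revolution: its radius field ``r(theta, z)`` is the pointwise maximum of a
tapered shaft profile and a superellipsoid-like condylar bulge with a mild
bicondylar azimuthal modulation, so the surface is closed and star-shaped
about the shaft axis by construction.  Tumors are icospheres with a radial
scaling field; lobed tumors modulate the radius with seeded low-order
spherical harmonics, clipped to stay star-shaped about the centroid so that
uniform margin expansion preserves containment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy.special import sph_harm_y

from .mesh_model import Scene, SurfaceMesh, points_in_mesh

__all__ = ["PhantomSpec", "InvalidSpecError", "make_scene", "make_suite",
           "export_phantom"]


class InvalidSpecError(ValueError):
    """Phantom specification cannot produce a usable scene."""


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic bone + tumor scene (all lengths mm).

    ``tumor_center`` is relative to the bone's axis midpoint;
    ``extraosseous_fraction`` > 0 pushes the tumor radially so roughly that
    fraction of its diameter protrudes through the cortex (a qualitative
    target, realized geometry depends on the local cortex curvature).
    """

    shaft_radius: float = 14.0
    shaft_length: float = 80.0
    condyle_bulge: float = 1.45
    taper: float = 0.15
    tumor_shape: str = "sphere"  # sphere | ellipsoid | lobed
    tumor_radii: tuple = (8.0, 8.0, 8.0)
    tumor_center: tuple = (0.0, 0.0, 0.0)
    extraosseous_fraction: float = 0.0
    mesh_resolution: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.shaft_radius, self.shaft_length) <= 0:
            raise InvalidSpecError("bone dimensions must be positive")
        if min(self.tumor_radii) <= 0:
            raise InvalidSpecError("tumor radii must be positive")
        if self.tumor_shape not in ("sphere", "ellipsoid", "lobed"):
            raise InvalidSpecError(
                f"unknown tumor shape {self.tumor_shape!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tumor_radii"] = list(d["tumor_radii"])
        d["tumor_center"] = list(d["tumor_center"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["tumor_radii"] = tuple(d["tumor_radii"])
        d["tumor_center"] = tuple(d["tumor_center"])
        return cls(**d)


# ---------------------------------------------------------------------------
# bone


def _bone_radius(theta: np.ndarray, z: np.ndarray,
                 spec: PhantomSpec) -> np.ndarray:
    """Radius field r(theta, z): max(tapered shaft, condylar bulge)."""
    L = spec.shaft_length
    u = (z + L / 2) / L  # 0 at distal end, 1 at condylar end
    shaft = spec.shaft_radius * (1.0 - spec.taper * (1.0 - u))
    # superellipsoid-like bulge occupying the top ~30% of the shaft
    h = 0.30 * L
    zc = L / 2 - h / 2
    s = np.clip(np.abs(z - zc) / (h / 2), 0.0, 1.0)
    profile = (1.0 - s ** 4) ** 0.25
    bicondylar = 1.0 + 0.12 * np.cos(2.0 * theta)
    bulge = spec.shaft_radius * spec.condyle_bulge * profile * bicondylar
    return np.maximum(shaft, bulge)


def _bone_mesh(spec: PhantomSpec) -> SurfaceMesh:
    n_theta = 24 * spec.mesh_resolution
    n_z = 30 * spec.mesh_resolution
    L = spec.shaft_length
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(-L / 2, L / 2, n_z)

    tt, zz = np.meshgrid(thetas, zs, indexing="ij")
    rr = _bone_radius(tt, zz, spec)
    ring = np.stack([rr * np.cos(tt), rr * np.sin(tt), zz], axis=-1)
    verts = ring.reshape(-1, 3)  # index = i_theta * n_z + i_z

    faces = []
    for i in range(n_theta):
        j = (i + 1) % n_theta
        for k in range(n_z - 1):
            a = i * n_z + k
            b = j * n_z + k
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    # end caps: fans to the axis points
    bot = len(verts)
    top = bot + 1
    verts = np.vstack([verts, [[0, 0, -L / 2], [0, 0, L / 2]]])
    for i in range(n_theta):
        j = (i + 1) % n_theta
        faces.append([bot, j * n_z, i * n_z])
        faces.append([top, i * n_z + n_z - 1, j * n_z + n_z - 1])

    tm = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                         process=True)
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), "bone")


# ---------------------------------------------------------------------------
# tumor


def _lobed_modulation(dirs: np.ndarray, rng) -> np.ndarray:
    """Low-order real spherical-harmonic radius modulation, star-shaped."""
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    mod = np.zeros(len(dirs))
    for ell in (2, 3, 4):
        for m in range(-ell, ell + 1):
            coef = rng.normal(0.0, 0.55 / ell)
            y = sph_harm_y(ell, abs(m), theta, phi)
            mod += coef * (np.real(y) if m >= 0 else np.imag(y))
    return np.clip(1.0 + mod, 0.40, 1.9)


def _tumor_mesh(spec: PhantomSpec) -> SurfaceMesh:
    # lobed shapes need enough vertices to resolve the l<=4 harmonics
    sub = max(2 if spec.tumor_shape == "lobed" else 1, spec.mesh_resolution)
    base = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    dirs = np.asarray(base.vertices)
    radii = np.asarray(spec.tumor_radii, float)
    verts = dirs * radii[None, :]
    if spec.tumor_shape == "sphere":
        verts = dirs * radii[0]
    elif spec.tumor_shape == "lobed":
        rng = np.random.default_rng(spec.seed)
        verts = dirs * radii[0] * _lobed_modulation(dirs, rng)[:, None]
    verts = verts + np.asarray(spec.tumor_center, float)
    return SurfaceMesh(verts, np.asarray(base.faces), "tumor")


def _analytic_volumes(spec: PhantomSpec, bone: SurfaceMesh,
                      tumor: SurfaceMesh) -> dict:
    a, b, c = spec.tumor_radii
    if spec.tumor_shape == "sphere":
        tumor_analytic = 4.0 / 3.0 * np.pi * a ** 3
    elif spec.tumor_shape == "ellipsoid":
        tumor_analytic = 4.0 / 3.0 * np.pi * a * b * c
    else:
        tumor_analytic = None  # no closed form for seeded lobed solids
    return {
        "tumor_analytic_volume": tumor_analytic,
        "tumor_mesh_volume": tumor.volume,
        "bone_mesh_volume": bone.volume,
    }


def make_scene(spec: PhantomSpec):
    """Build the phantom's watertight meshes (pre-voxelization).

    Returns ``(scene, info)`` where ``scene`` carries the bone and tumor
    meshes (``voxels`` unset) and ``info`` reports the analytic volumes of
    the primitive solids alongside the mesh volumes.  Deterministic for a
    given spec/seed.

    Raises
    ------
    InvalidSpecError
        If the tumor does not intersect the bone.
    """
    bone = _bone_mesh(spec)
    tumor = _tumor_mesh(spec)
    probes = np.vstack([tumor.vertices, tumor.centroid[None, :]])
    if not points_in_mesh(probes, bone).any():
        raise InvalidSpecError(
            "tumor does not intersect the bone: no intracortical volume")
    return Scene(bone, tumor, None), _analytic_volumes(spec, bone, tumor)


def _eccentric_center(spec_radius: float, tumor_r: float,
                      frac: float, z: float, azimuth: float) -> tuple:
    """Radial placement pushing ~frac of the tumor diameter past the cortex."""
    d = spec_radius - tumor_r + 2.0 * tumor_r * frac
    return (d * np.cos(azimuth), d * np.sin(azimuth), z)


def make_suite(n: int, seed: int = 0) -> list:
    """Generate ``n`` phantom specs spanning a realistic case diversity.

    Cycles through tumor size classes (small/medium/large relative to the
    shaft), centered vs eccentric placement, with and without extraosseous
    extension, with seeded jitter.  Most tumors are lobed — segmented tumor
    meshes are irregular, and the tumor-to-hull gap adds a shape-driven
    component to the waste on top of the cone's unavoidable exit path —
    with one sphere and one ellipsoid case kept as convex controls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    size_frac = (0.45, 0.60, 0.78)
    specs = []
    for i in range(n):
        shaft_r = 13.0 + rng.uniform(-1.0, 2.0)
        shaft_len = 78.0 + rng.uniform(-6.0, 8.0)
        frac = size_frac[i % 3]
        r = frac * shaft_r
        shape = {2: "sphere", 4: "ellipsoid"}.get(i % 6, "lobed")
        radii = (r, r, r)
        if shape == "ellipsoid":
            radii = (r, 0.8 * r, 1.25 * r)
        eccentric = (i // 3) % 2 == 1
        breach = i % 2 == 1
        z = rng.uniform(-0.15, 0.25) * shaft_len
        if eccentric:
            ex_frac = 0.3 if breach else 0.0
            center = _eccentric_center(shaft_r, r, ex_frac, z,
                                       rng.uniform(0, 2 * np.pi))
        else:
            center = (0.0, 0.0, z)
            ex_frac = 0.0
        specs.append(PhantomSpec(
            shaft_radius=shaft_r, shaft_length=shaft_len,
            tumor_shape=shape, tumor_radii=radii, tumor_center=center,
            extraosseous_fraction=ex_frac,
            mesh_resolution=1, seed=int(rng.integers(0, 2 ** 31 - 1))))
    return specs


def export_phantom(spec: PhantomSpec, out_dir, fmt: str = "ply") -> dict:
    """Write the phantom mesh pair plus a JSON sidecar with the spec/volumes."""
    import json
    from pathlib import Path

    from .mesh_model import save_mesh

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene, info = make_scene(spec)
    bone_path = out / f"bone.{fmt}"
    tumor_path = out / f"tumor.{fmt}"
    save_mesh(scene.bone_mesh, bone_path)
    save_mesh(scene.tumor_mesh, tumor_path)
    sidecar = {"spec": spec.to_dict(), "volumes": info}
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return {"bone": str(bone_path), "tumor": str(tumor_path),
            "sidecar": str(out / "phantom.json")}
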