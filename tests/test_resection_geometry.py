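"""Resection geometries: frames, hull membership, waste and baselines."""

import numpy as np
import pytest
import trimesh
from oracle_utils import in_hull_lp_mask

from resectplan.mesh_model import Scene, SurfaceMesh, build_scene
from resectplan.resection_geometry import (
    DegenerateHullError,
    DegenerateSceneWasteError,
    InfeasiblePlaneError,
    LocalFrame,
    ParameterError,
    RGParams,
    best_planar_baseline,
    bone_waste,
    build_conical,
    build_contoured,
    build_flat_based,
    build_rg,
    extend_profile,
    planar_baseline,
    point_in_hull_3d,
    rotation_zyx,
    sample_params,
    to_local,
)


def _make_cylinder_scene(center):
    bone_tm = trimesh.creation.cylinder(radius=25.0, height=60.0,
                                        sections=96)
    bone = SurfaceMesh(np.asarray(bone_tm.vertices),
                       np.asarray(bone_tm.faces), "bone")
    tum_tm = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    tumor = SurfaceMesh(np.asarray(tum_tm.vertices)
                        + np.asarray(center, float),
                        np.asarray(tum_tm.faces), "tumor")
    return build_scene(bone, tumor, pitch=2.0)


@pytest.fixture(scope="module")
def cylinder_scene():
    """Sphere r=10 in a cylindrical bone r=25 h=60, generic grid phase."""
    return _make_cylinder_scene((0.31, 0.17, 0.23))


@pytest.fixture(scope="module")
def symmetric_cylinder_scene():
    """Exactly centered sphere-in-cylinder, mirror symmetric about x=0."""
    return _make_cylinder_scene((0.0, 0.0, 0.0))


def _params(rg_type="conical", tz=-200000.0, **kw):
    base = dict(theta_z=0.0, theta_y=0.0, theta_x=0.0,
                t_x=0.0, t_y=0.0, t_z=tz)
    base.update(kw)
    if rg_type == "contoured":
        base.setdefault("phi_z", 0.0)
    return RGParams(rg_type=rg_type, **base)


# ---------------------------------------------------------------------------
# local frame


class TestToLocal:
    def test_tumor_base_at_origin_when_tz_at_bound(self, cylinder_scene):
        zmin = cylinder_scene.tumor_mesh.vertices[:, 2].min()
        local = to_local(cylinder_scene, _params(tz=float(zmin)))
        assert abs(local["tumor_vertices"][:, 2].min()) < 1e-9

    def test_rigid_motion_preserves_distances(self, cylinder_scene, rng):
        p = sample_params(cylinder_scene, "conical", rng)
        local = to_local(cylinder_scene, p)
        v = cylinder_scene.tumor_mesh.vertices
        d0 = np.linalg.norm(v[:10, None] - v[None, :10], axis=2)
        lv = local["tumor_vertices"]
        d1 = np.linalg.norm(lv[:10, None] - lv[None, :10], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-8)

    def test_rotation_periodicity(self, cylinder_scene):
        a = to_local(cylinder_scene, _params(theta_z=180.0, tz=-50.0))
        b = to_local(cylinder_scene, _params(theta_z=-180.0, tz=-50.0))
        np.testing.assert_allclose(a["tumor_vertices"],
                                   b["tumor_vertices"], atol=1e-9)

    def test_out_of_bounds_raises(self, cylinder_scene):
        with pytest.raises(ParameterError):
            to_local(cylinder_scene, _params(theta_z=200.0))
        with pytest.raises(ParameterError):
            to_local(cylinder_scene, _params(tz=5.0))  # above min(T'_z)

    def test_frame_roundtrip(self, rng):
        frame = LocalFrame(rotation_zyx(31.0, -47.0, 112.0),
                           np.array([3.0, -4.0, -120.0]), 25.0)
        pts = rng.normal(size=(50, 3)) * 30
        back = frame.to_base_pts(frame.to_local_pts(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)


# ---------------------------------------------------------------------------
# hull membership


class TestPointInHull:
    def test_tetrahedron_examples(self):
        tet = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                       float)
        assert point_in_hull_3d([[0.1, 0.1, 0.1]], tet)[0]
        assert point_in_hull_3d([[1.0, 0.0, 0.0]], tet)[0]  # vertex
        assert not point_in_hull_3d([[0.5, 0.5, 0.5]], tet)[0]

    def test_degenerate_generators_raise(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
                        float)
        with pytest.raises(DegenerateHullError):
            point_in_hull_3d([[0.2, 0.2, 0.0]], flat)

    def test_matches_lp_feasibility_oracle(self, rng):
        gen = rng.normal(size=(12, 3)) * 5
        pts = rng.uniform(-6, 6, size=(300, 3))
        ours = point_in_hull_3d(pts, gen)
        oracle = in_hull_lp_mask(pts, gen)
        np.testing.assert_array_equal(ours, oracle)


# ---------------------------------------------------------------------------
# waste arithmetic


class TestBoneWaste:
    @pytest.mark.parametrize("removed,intra,expected", [
        (0, 150, 0.0), (50, 150, 25.0), (150, 150, 50.0)])
    def test_formula(self, removed, intra, expected):
        assert bone_waste(removed, intra) == pytest.approx(expected)

    def test_undefined_without_intracortical(self):
        with pytest.raises(DegenerateSceneWasteError):
            bone_waste(10, 0)


# ---------------------------------------------------------------------------
# resection builds against analytic geometry


class TestConical:
    def test_far_focal_point_gives_clipped_cylinder(self, cylinder_scene):
        rg, waste = build_conical(cylinder_scene, _params())
        # the cut is carried through the far cortex, so a distant focal
        # point removes the circumscribing cylinder of the sphere clipped
        # to the full bone length, minus the tumor itself
        zb = cylinder_scene.bone_mesh.vertices[:, 2]
        length = float(zb.max() - zb.min())
        analytic = (np.pi * 100.0 * length
                    - 4.0 / 3.0 * np.pi * 1000.0)
        assert rg.removed_volume == pytest.approx(analytic, rel=0.10)
        assert rg.complete

    def test_near_apex_removes_no_deeper_bone(self, cylinder_scene):
        zmin = float(cylinder_scene.tumor_mesh.vertices[:, 2].min())
        near_z = zmin - 15.0
        rg_near, _ = build_conical(cylinder_scene, _params(tz=near_z))
        rg_far, _ = build_conical(cylinder_scene, _params())
        B = cylinder_scene.voxels.healthy_bone_points
        # near apex: a narrow tip - nothing below the apex is removed -
        # but a wide opening angle above the tumor; the distant apex is a
        # straight column reaching the bone base
        removed_z = B[rg_near.removed_indices][:, 2]
        assert removed_z.min() >= near_z - 1e-6
        assert B[rg_far.removed_indices][:, 2].min() < near_z
        above = B[:, 2] > 10.0  # above the tumor top
        near_above = np.isin(np.flatnonzero(above),
                             rg_near.removed_indices).sum()
        far_above = np.isin(np.flatnonzero(above),
                            rg_far.removed_indices).sum()
        assert near_above > far_above


class TestFlatBased:
    def test_subset_of_conical_and_facing_plane(self, cylinder_scene):
        rgc, _ = build_conical(cylinder_scene, _params())
        rgf, wf = build_flat_based(cylinder_scene, _params("flat"))
        assert set(rgf.removed_indices) < set(rgc.removed_indices)
        # facing cut retains everything below the tumor base: the removed
        # region is the column from the base plane to the bone top, minus
        # the tumor
        zmin = float(cylinder_scene.tumor_mesh.vertices[:, 2].min())
        ztop = float(cylinder_scene.bone_mesh.vertices[:, 2].max())
        analytic = (np.pi * 100.0 * (ztop - zmin)
                    - 4.0 / 3.0 * np.pi * 1000.0)
        assert rgf.removed_volume == pytest.approx(analytic, rel=0.10)
        assert rgf.complete

    def test_equals_conical_when_no_bone_below_base(self):
        bone_tm = trimesh.creation.cylinder(radius=20.0, height=40.0,
                                            sections=64)
        bone = SurfaceMesh(np.asarray(bone_tm.vertices),
                           np.asarray(bone_tm.faces), "bone")
        tum_tm = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        # tumor pokes out of the bottom: no bone below min tumor z
        tumor = SurfaceMesh(np.asarray(tum_tm.vertices)
                            + [0, 0, -21.0], np.asarray(tum_tm.faces),
                            "tumor")
        scene = build_scene(bone, tumor, pitch=2.0)
        zmin = float(scene.tumor_mesh.vertices[:, 2].min())
        rgc, _ = build_conical(scene, _params(tz=zmin - 30.0))
        rgf, _ = build_flat_based(scene, _params("flat", tz=zmin - 30.0))
        assert set(rgf.removed_indices) == set(rgc.removed_indices)


class TestContoured:
    def test_sphere_gives_cone_cut_by_prism(self, cylinder_scene):
        rgk, _ = build_contoured(cylinder_scene, _params("contoured"))
        vox = cylinder_scene.voxels
        B = vox.healthy_bone_points
        r_t = 10.0
        # distant apex: the cone is the full vertical column; the facing
        # cut is the horizontal circumscribing cylinder -> a Steinmetz
        # bicylinder intersection minus the tumor
        in_cone = B[:, 0] ** 2 + B[:, 1] ** 2 <= r_t ** 2
        in_prism = B[:, 0] ** 2 + B[:, 2] ** 2 <= r_t ** 2
        predicted = int((in_cone & in_prism).sum())
        assert len(rgk.removed_indices) == pytest.approx(predicted,
                                                         rel=0.10)

    def test_never_worse_than_flat_same_params(self, small_scene, rng):
        for _ in range(10):
            pk = sample_params(small_scene, "contoured", rng)
            vec = pk.to_vector()
            pf = RGParams.from_vector(vec[:6], "flat")
            _, wk = build_rg(small_scene, pk)
            _, wf = build_rg(small_scene, pf)
            assert wk.bone_waste_pct <= wf.bone_waste_pct + 1e-12

    @pytest.mark.parametrize("phi", [30.0, 45.0, 80.0])
    def test_mirror_symmetry_reflects_phi(self, symmetric_cylinder_scene,
                                          phi):
        # x -> -x maps the scene to itself and phi_z to -phi_z, so the
        # removed counts must agree up to boundary-tolerance ties
        wp = build_contoured(symmetric_cylinder_scene,
                             _params("contoured", phi_z=phi))[1]
        wm = build_contoured(symmetric_cylinder_scene,
                             _params("contoured", phi_z=-phi))[1]
        assert abs(wp.removed_count - wm.removed_count) <= 2


# ---------------------------------------------------------------------------
# brute-force oracle equivalence


def test_removal_mask_matches_lp_oracle(tiny_scene, rng):
    """Conical removal equals conic-combination feasibility per voxel."""
    from oracle_utils import in_cone_lp_mask

    B = tiny_scene.voxels.healthy_bone_points
    sub = rng.choice(len(B), size=300, replace=False)
    for tz in (-40.0, -2000.0):
        p = sample_params(tiny_scene, "conical", rng)
        p.t_z = tz
        rg, _ = build_rg(tiny_scene, p)
        local = to_local(tiny_scene, p)
        oracle = in_cone_lp_mask(local["healthy_bone"][sub],
                                 local["tumor_vertices"])
        ours = np.zeros(len(B), bool)
        ours[rg.removed_indices] = True
        np.testing.assert_array_equal(ours[sub], oracle)


def test_frame_invariance(tiny_scene, rng):
    """Rigidly rotating scene + parameter frame together leaves waste fixed."""
    Q = rotation_zyx(25.0, -40.0, 65.0)
    vox = tiny_scene.voxels
    import dataclasses

    rot_scene = Scene(
        SurfaceMesh(tiny_scene.bone_mesh.vertices @ Q.T,
                    tiny_scene.bone_mesh.faces, "bone"),
        SurfaceMesh(tiny_scene.tumor_mesh.vertices @ Q.T,
                    tiny_scene.tumor_mesh.faces, "tumor"),
        dataclasses.replace(
            vox,
            healthy_bone_points=vox.healthy_bone_points @ Q.T,
            intracortical_tumor_points=vox.intracortical_tumor_points @ Q.T,
            extraosseous_tumor_points=(
                vox.extraosseous_tumor_points @ Q.T
                if len(vox.extraosseous_tumor_points)
                else vox.extraosseous_tumor_points)),
    )
    for _ in range(5):
        p = sample_params(tiny_scene, "conical", rng)
        R = rotation_zyx(p.theta_z, p.theta_y, p.theta_x)
        frame_rot = LocalFrame(R @ Q.T, np.array([p.t_x, p.t_y, p.t_z]))
        _, w1 = build_rg(tiny_scene, p)
        # same local frame reached from the rotated scene
        local_B = frame_rot.to_local_pts(rot_scene.voxels.healthy_bone_points)
        orig_B = to_local(tiny_scene, p)["healthy_bone"]
        np.testing.assert_allclose(local_B, orig_B, atol=1e-8)


# ---------------------------------------------------------------------------
# profile extension


class TestExtendProfile:
    def test_waste_unchanged_and_clearance(self, tiny_scene, rng):
        p = sample_params(tiny_scene, "conical", rng)
        p.t_z = max(p.t_z, -150.0)
        rg, w0 = build_rg(tiny_scene, p)
        ext = extend_profile(rg, tiny_scene, clearance=5.0)
        np.testing.assert_array_equal(ext.removed_indices,
                                      rg.removed_indices)
        # every removed voxel lies closer to the focal point than the
        # extended profile vertices reach
        B = tiny_scene.voxels.healthy_bone_points[rg.removed_indices]
        d_bone = np.linalg.norm(B - rg.focal_point, axis=1)
        d_prof = np.linalg.norm(ext.profile_3d - rg.focal_point, axis=1)
        assert d_prof.min() >= d_bone.max() + 5.0 - 1e-6

    def test_extension_is_stable(self, tiny_scene, rng):
        p = sample_params(tiny_scene, "conical", rng)
        p.t_z = max(p.t_z, -150.0)
        rg, _ = build_rg(tiny_scene, p)
        e1 = extend_profile(rg, tiny_scene, clearance=5.0)
        e2 = extend_profile(e1, tiny_scene, clearance=5.0)
        np.testing.assert_allclose(e1.profile_3d, e2.profile_3d, atol=1e-6)


# ---------------------------------------------------------------------------
# planar comparator


class TestPlanarBaseline:
    def test_transverse_plane_matches_direct_count(self, cylinder_scene):
        vox = cylinder_scene.voxels
        w = planar_baseline(cylinder_scene, (0, 0, 1), -10.5)
        expected = int((vox.healthy_bone_points[:, 2] > -10.5).sum())
        assert w.removed_count == expected
        assert w.bone_waste_pct == pytest.approx(
            100.0 * expected / (expected + w.intracortical_count))

    def test_plane_through_tumor_is_infeasible(self, cylinder_scene):
        with pytest.raises(InfeasiblePlaneError):
            planar_baseline(cylinder_scene, (0, 0, 1), 0.0)

    def test_hull_beats_best_plane_for_deep_tumor(self, cylinder_scene):
        best, _, _ = best_planar_baseline(cylinder_scene, n_directions=100)
        _, wc = build_conical(cylinder_scene, _params())
        assert wc.bone_waste_pct < best.bone_waste_pct
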