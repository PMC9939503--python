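import numpy as np
import pytest

from resectplan.mesh_model import build_scene
from resectplan.phantom import PhantomSpec, make_scene, make_suite


def scene_from_spec(spec: PhantomSpec, pitch: float = 2.0):
    scene, _ = make_scene(spec)
    return build_scene(scene.bone_mesh, scene.tumor_mesh, pitch=pitch)


@pytest.fixture(scope="session")
def suite_specs():
    return make_suite(10, seed=11)


@pytest.fixture(scope="session")
def small_scene(suite_specs):
    """One lobed-tumor phantom scene, voxelized at the working pitch."""
    return scene_from_spec(suite_specs[0])


@pytest.fixture(scope="session")
def tiny_scene():
    """A <= 3000-healthy-voxel scene for optimizer/oracle comparisons."""
    spec = PhantomSpec(shaft_radius=9.5, shaft_length=55.0,
                       condyle_bulge=1.3, tumor_shape="lobed",
                       tumor_radii=(5.5, 5.5, 5.5),
                       tumor_center=(0.0, 0.0, 5.0),
                       mesh_resolution=1, seed=4)
    scene = scene_from_spec(spec)
    assert len(scene.voxels.healthy_bone_points) <= 3000
    return scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
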