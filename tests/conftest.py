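import numpy as np
import pytest

from guidefit.experiments import build_reference_scene, desk_phantom_params
from guidefit.phantom import CTSimParams, make_synthetic_radius
from guidefit.pose_error import anatomic_frame


@pytest.fixture(scope="session")
def desk_params():
    return desk_phantom_params(seed=3)


@pytest.fixture(scope="session")
def desk_bone(desk_params):
    """One deterministic reduced-size radius phantom (mesh, landmarks)."""
    return make_synthetic_radius(desk_params)


@pytest.fixture(scope="session")
def desk_frame(desk_bone):
    mesh, landmarks = desk_bone
    return anatomic_frame(mesh, landmarks["styloid_tip"])


@pytest.fixture(scope="session")
def reference_scene(desk_params):
    """Reference model (bone + standard guides, default CT sim) fully measured."""
    return build_reference_scene(phantom=desk_params, sim=CTSimParams(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
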