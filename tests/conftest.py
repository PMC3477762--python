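import numpy as np
import pytest

from kneedea import build_scene
from kneedea.phantom import generate_knee_phantom, place_in_scene
from kneedea.projection import render_silhouette


@pytest.fixture(scope="session")
def knee_phantom():
    """Default asymmetric knee phantom (femur, tibia, truth pose)."""
    return generate_knee_phantom()


@pytest.fixture(scope="session")
def fast_scene():
    """Coarse scene (0.4 mm pixels, 512^2) for quick registration tests."""
    return build_scene(caudal_angle=10, pixel_spacing=0.4, image_size=(512, 512))


@pytest.fixture(scope="session")
def placed_femur(knee_phantom, fast_scene):
    femur, _, _ = knee_phantom
    return place_in_scene(femur, fast_scene)


@pytest.fixture(scope="session")
def femur_edges(placed_femur, fast_scene):
    """Self-rendered femur edge image at the identity truth pose."""
    return render_silhouette(placed_femur, fast_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
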