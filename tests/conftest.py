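import numpy as np
import pytest

from bivos import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_spec():
    return SceneSpec(n_animals=2, n_frames=30, height=64, width=80, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    """A clean two-animal scene shared by read-only tests."""
    return generate_scene(small_spec)


def two_animal_frame(h=20, w=20, sep=6, size=4):
    """A label image with two disjoint square animals, ``sep`` pixels apart."""
    frame = np.zeros((h, w), dtype=np.uint8)
    frame[2 : 2 + size, 2 : 2 + size] = 1
    frame[2 : 2 + size, 2 + size + sep : 2 + 2 * size + sep] = 2
    return frame


@pytest.fixture
def disjoint_frame():
    return two_animal_frame()
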