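import numpy as np
import pandas as pd
import pytest

from matpercept.core_data import ATTRIBUTES, panel_from_arrays
from matpercept.synthetic import SyntheticConfig, generate_cube_image, generate_panel


@pytest.fixture(scope="session")
def default_panels():
    """The default-size synthetic (color, grayscale) pair, seed 1."""
    return generate_panel(SyntheticConfig(seed=1))


SMALL_CONFIG = SyntheticConfig(
    n_images=60, n_observers_binary=8, n_observers_category=6, seed=2
)


@pytest.fixture(scope="session")
def small_panels():
    return generate_panel(SMALL_CONFIG)


@pytest.fixture(scope="session")
def cube():
    """Default Beer-Lambert cube stimulus: (uint8 image, mask)."""
    return generate_cube_image(seed=0)


def make_tiny_panel(condition="color"):
    """2 observers x 2 images with hand-written ratings."""
    binary = np.array([[1, 0], [0, 0]])
    ratings = pd.DataFrame(
        [
            {"observer_id": o, "image_id": i, **{a: r for a in ATTRIBUTES}}
            for (o, i, r) in [
                ("o1", "imgA", 3),
                ("o1", "imgB", 1),
                ("o2", "imgA", 6),
                ("o2", "imgB", 2),
            ]
        ]
    )
    categories = pd.DataFrame(
        [
            {"observer_id": "o1", "image_id": "imgA", "category": "wax"},
            {"observer_id": "o1", "image_id": "imgB", "category": "glass"},
        ]
    )
    ground_truth = pd.Series({"imgA": "wax", "imgB": "metal"})
    return panel_from_arrays(
        condition, ["o1", "o2"], ["imgA", "imgB"], binary, ratings, categories, ground_truth
    )
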