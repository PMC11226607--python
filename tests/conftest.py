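import numpy as np
import pytest

from pndnet import SyntheticSpec, generate_dataset, generate_images


@pytest.fixture(scope="session")
def leaf3():
    """3-class, 20-images-per-class, 64px synthetic fixture (arrays)."""
    spec = SyntheticSpec(n_classes=3, images_per_class=20, image_size=64, seed=7)
    X, y = generate_images(spec)
    return X, y


@pytest.fixture(scope="session")
def leaf8_tree(tmp_path_factory):
    """8-class, 4-images-per-class, 64px class-per-folder tree on disk."""
    root = tmp_path_factory.mktemp("leaf8")
    spec = SyntheticSpec(n_classes=8, images_per_class=4, image_size=64, seed=11)
    generate_dataset(spec, root)
    return root


@pytest.fixture
def rng():
    return np.random.default_rng(42)
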