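import numpy as np
import pytest

from ievit.synthetic import SyntheticDatasetSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small clutter-free 3-class dataset shared by pipeline tests."""
    root = tmp_path_factory.mktemp("tinydata")
    spec = SyntheticDatasetSpec(num_classes=3, images_per_class=6,
                                image_size=40, clutter=0.0, seed=11)
    manifest = generate_dataset(spec, root)
    return root, manifest, spec
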