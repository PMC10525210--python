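import numpy as np
import pytest
from PIL import Image

from asnet import fixtures


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_image_dataset(tmp_path_factory):
    """40-sample two-class phantom PNG dataset (shared, read-only)."""
    root = tmp_path_factory.mktemp("phantoms")
    spec = fixtures.FixtureSpec(n_per_class=20, delta=6.0, seed=7)
    manifest = fixtures.gen_image_dataset(spec, root)
    return root, manifest


@pytest.fixture()
def tiny_class_dir(tmp_path):
    """Directory with AS/ (3 files) and control/ (2 files) of small PNGs."""
    rng = np.random.default_rng(0)
    for cls, count in (("AS", 3), ("control", 2)):
        d = tmp_path / cls
        d.mkdir()
        for i in range(count):
            arr = rng.integers(0, 255, size=(8, 8), dtype=np.uint8)
            Image.fromarray(arr, mode="L").save(d / f"{cls}{i}.png")
    return tmp_path
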