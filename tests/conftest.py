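import numpy as np
import pytest
from scipy import ndimage

from mribovw import GrayImage, PipelineConfig, make_dataset
from mribovw.pipeline import HybridBovwModel


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def textured_image(rng):
    """Smooth random texture spanning most of [0, 1]."""
    raw = ndimage.gaussian_filter(rng.standard_normal((96, 96)), 2.0)
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    return GrayImage(raw)


@pytest.fixture(scope="session")
def phantom_root(tmp_path_factory):
    """Small phantom dataset shared by pipeline-level tests."""
    root = tmp_path_factory.mktemp("phantoms")
    make_dataset(8, root, seed=11)
    return root


@pytest.fixture(scope="session")
def small_results(phantom_root):
    """One fitted small pipeline reused across tests (k=32 words)."""
    cfg = PipelineConfig(vocab_k=32, split_seed=11, kmeans_seed=11)
    model = HybridBovwModel.from_folder(phantom_root, cfg)
    return model.fit(evaluate_single_families=True, keep_features=True)
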