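import numpy as np
import pytest

from endoml.enhancement import ContrastEnhancer
from endoml.synthdata import FrameRecipe, TableRecipe, make_frames, make_table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_frames():
    """Twenty 96x96 two-class frames with ground-truth masks."""
    return make_frames(FrameRecipe(n_frames=20, seed=0))


@pytest.fixture(scope="session")
def enhanced_frames(small_frames):
    images, _, _ = small_frames
    return ContrastEnhancer().transform(images)


@pytest.fixture(scope="session")
def planted_table():
    return make_table(TableRecipe(n=200, d=50, k=5, effect=2.0, seed=0))


@pytest.fixture(scope="session")
def trained_segmenter(small_frames):
    """Saliency segmenter trained once on the shared frame fixture."""
    from endoml.saliency import SaliencySegmenter

    images, _, labels = small_frames
    return SaliencySegmenter(epochs=60, random_state=0).fit(images, labels)
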