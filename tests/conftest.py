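import numpy as np
import pytest

from tsrquant.agreement import ConfusionTable
from tsrquant.synthdata import ImageScene, generate_wholemount

# Full-canvas rectangle ROI: exactly one 512x512 tile of area, the smallest
# ROI the generator accepts, which keeps image-based tests cheap.
RECT_512 = ((0.0, 0.0), (0.0, 512.0), (512.0, 512.0), (512.0, 0.0))


@pytest.fixture(scope="session")
def agreement_table() -> ConfusionTable:
    """The published computer-vs-pathologist 2x2 table (n=41)."""
    return ConfusionTable(a=17, b=1, c=3, d=20)


@pytest.fixture(scope="session")
def wholemount_060():
    """One synthetic whole-mount at 60% target epithelium, default noise."""
    scene = ImageScene(target_epithelium_fraction=0.60, seed=7)
    rgb, truth, roi = generate_wholemount(scene)
    return scene, rgb, truth, roi


@pytest.fixture(scope="session")
def noisefree_wholemount():
    """A noise-free slide (stain colors exactly at their class means)."""
    from tsrquant.synthdata import StainParams

    scene = ImageScene(
        canvas_height=512, canvas_width=512, roi_polygon=RECT_512,
        target_epithelium_fraction=0.5,
        stain_params=StainParams(noise_sd=0.0), seed=11,
    )
    rgb, truth, roi = generate_wholemount(scene)
    return scene, rgb, truth, roi


def random_label_mask(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.integers(0, 3, size=shape).astype(np.uint8)
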