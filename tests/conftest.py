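import numpy as np
import pytest

from liverdwi import PhantomConfig, generate_slice
from liverdwi.qscore import RoiSet


@pytest.fixture(scope="session")
def clean_slice():
    """Artifact-free, noise-free phantom slice (every repetition == truth)."""
    cfg = PhantomConfig(
        height=64, width=64, dropout_prob=0.0, flicker_prob=0.0, noise_sigma=0.0,
        seed=5,
    )
    return generate_slice(cfg)


@pytest.fixture(scope="session")
def artifact_slice():
    """Default-config phantom slice with dropouts, flicker and noise."""
    return generate_slice(PhantomConfig(seed=42))


@pytest.fixture()
def toy_rois():
    """Hand-built 6x6 ROI set with known voxel counts."""
    z = np.zeros((6, 6), dtype=bool)
    left = z.copy()
    left[1:5, 0:2] = True
    right = z.copy()
    right[1:5, 3:6] = True
    vessels = z.copy()
    vessels[2, 4] = True
    lesions = z.copy()
    lesions[1, 3] = True
    background = z.copy()
    background[3:5, 3:6] = True
    return RoiSet(
        left_lobe=left,
        right_lobe=right,
        vessels=vessels,
        lesions=lesions,
        background=background,
    )
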