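import numpy as np
import pytest

from ovimorph.mask_io import BinaryMask
from ovimorph.synthetic import (PITCH_DOWN, PITCH_UP, SilhouetteParams,
                                make_silhouette)


@pytest.fixture(scope="session")
def head_down_truth():
    """Default lowered-head silhouette with ground truth."""
    return make_silhouette(SilhouetteParams(head_pitch=PITCH_DOWN), seed=0)


@pytest.fixture(scope="session")
def head_up_truth():
    """Default raised-head silhouette with ground truth."""
    return make_silhouette(SilhouetteParams(head_pitch=PITCH_UP), seed=0)


@pytest.fixture(scope="session")
def jump_truth():
    """Strongly tilted (jumping) silhouette with ground truth."""
    return make_silhouette(
        SilhouetteParams(head_pitch=PITCH_DOWN, body_tilt=20.0), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def solid_mask(w: int, h: int, x0: int, y0: int, x1: int, y1: int) -> BinaryMask:
    """Frame of w x h with a solid rectangle [x0,x1) x [y0,y1)."""
    g = np.zeros((h, w), dtype=bool)
    g[y0:y1, x0:x1] = True
    return BinaryMask(g)


def brute_force_max_rect(grid: np.ndarray):
    """O(n^4) exhaustive maximal all-true rectangle, tie-break smallest
    (y0, x0, y1, x1); independent oracle for the stack algorithm."""
    h, w = grid.shape
    best = None
    for y0 in range(h):
        for y1 in range(y0 + 1, h + 1):
            for x0 in range(w):
                for x1 in range(x0 + 1, w + 1):
                    if grid[y0:y1, x0:x1].all():
                        key = (-(y1 - y0) * (x1 - x0), y0, x0, y1, x1)
                        if best is None or key < best:
                            best = key
    return None if best is None else best[1:]
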