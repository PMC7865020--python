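import numpy as np
import pytest
from hypothesis import settings

from schooltrack import BoundingBox

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def box():
    def make(x0, y0, x1, y1, frame=0):
        return BoundingBox(x0, y0, x1, y1, frame=frame)

    return make


def rasterized_min_intersection(a: BoundingBox, b: BoundingBox, step=0.5) -> float:
    """Independent pixel-set oracle for intersection-over-minimum-area."""

    def cells(bb):
        xs = np.arange(bb.x_min, bb.x_max, step)
        ys = np.arange(bb.y_min, bb.y_max, step)
        return {(round(x, 4), round(y, 4)) for x in xs for y in ys}

    ca, cb = cells(a), cells(b)
    inter = len(ca & cb) * step * step
    return inter / min(a.area, b.area)
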