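import numpy as np
import pytest

from vesiquant.migration import Track
from vesiquant.shape import Contour
from vesiquant.stvariance import FrameStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def constant_stack():
    return FrameStack(
        data=np.full((5, 16, 16), 7.0), frame_interval=0.3, pixel_size=0.065
    )


@pytest.fixture
def two_frame_stack():
    """Normalized 2-frame fixture: pixel A (0.5, 1.5), pixel B (1.5, 0.5)."""
    data = np.array([[[0.5, 1.5]], [[1.5, 0.5]]])
    return FrameStack(data=data, frame_interval=0.3, pixel_size=0.065)


def straight_track(v=1.0, n=11, dt=1.0, angle=0.0, **kw):
    t = np.arange(n) * dt
    d = np.array([np.cos(angle), np.sin(angle)])
    return Track(cell_id=kw.pop("cell_id", "c"), t=t, xy=np.outer(v * t, d), **kw)


@pytest.fixture
def ellipse_contour():
    def make(a=10.0, b=5.0, n=360, **kw):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return Contour(
            vertices=np.column_stack([a * np.cos(t), b * np.sin(t)]), **kw
        )

    return make
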