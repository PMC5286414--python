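import numpy as np
import pytest

from nichespace.datamodel import AxisDescriptor, CommunityMatrix


def make_community(points, axis_names=None, taxa=None, axes=None):
    """Build a CommunityMatrix from a plain (S, n) array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s, n = pts.shape
    if axes is None:
        names = axis_names or [f"axis{j + 1}" for j in range(n)]
        axes = tuple(AxisDescriptor(str(nm)) for nm in names)
    taxa = tuple(taxa or [f"sp{i + 1}" for i in range(s)])
    return CommunityMatrix(taxa, axes, pts)


@pytest.fixture
def triangle():
    """The canonical right-triangle community: (0,0), (1,0), (0,1)."""
    return make_community([[0, 0], [1, 0], [0, 1]])


@pytest.fixture
def random_community():
    def _make(s, n, seed=0, scale=10.0):
        rng = np.random.default_rng(seed)
        return make_community(rng.normal(0.0, scale, (s, n)))

    return _make
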