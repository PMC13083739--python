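import numpy as np
import pytest

from petmoco.frames import FrameTiming
from petmoco.phantom import make_phantom


@pytest.fixture(scope="session")
def phantom40():
    """Shared mid-size FDG-like phantom (40^3 voxels, 3.5 mm)."""
    return make_phantom((40, 40, 40), 3.5, "fdg_like", seed=7)


@pytest.fixture(scope="session")
def phantom_met40():
    return make_phantom((40, 40, 40), 3.5, "met_like", seed=7)


@pytest.fixture(scope="session")
def phantom32():
    """Smallest admissible phantom for cheap tests."""
    return make_phantom((32, 32, 32), 4.0, "fdg_like", seed=7)


@pytest.fixture()
def timing6():
    return FrameTiming.uniform(6, 30.0)


def probe_errors(est, true, brain_center, offset_mm=70.0):
    """Per-frame, per-probe distance between estimated and true probe positions."""
    center = np.asarray(brain_center, dtype=float)
    probes = [center + np.array([0.0, offset_mm, 0.0]),
              center - np.array([0.0, offset_mm, 0.0])]
    errs = []
    for te, tt in zip(est.transforms, true.transforms):
        for p in probes:
            errs.append(np.linalg.norm(te.apply(p) - tt.apply(p)))
    return np.asarray(errs)
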