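import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from avleak import phantom
from avleak.paths import VesselPath
from avleak.phantom import PhantomSpec, PhantomTruth
from avleak.stack import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(20251)


@pytest.fixture
def tube_scene():
    """A noise-free 20 µm tube along x in a small stack, with truth."""
    rng = np.random.default_rng(7)
    from avleak.validation import single_tube_scene

    spec, truth = single_tube_scene(20.0, rng, "Ae", length_um=30.0)
    stack = phantom.render(truth, spec)
    return spec, truth, stack


def straight_tube_stack(
    diameter_um=8.0,
    shape=(24, 40, 40),
    voxel=(1.0, 0.58, 0.58),
    intensity=100.0,
    cz=None,
    cy=None,
):
    """Analytic cylinder along x (no PSF, no partial volume) for low-level
    tests; returns (stack, center_zy, radius)."""
    vz, vy, vx = voxel
    zz = (np.arange(shape[0]) + 0.5) * vz
    yy = (np.arange(shape[1]) + 0.5) * vy
    cz = zz.mean() if cz is None else cz
    cy = yy.mean() if cy is None else cy
    r = diameter_um / 2.0
    dist2 = (zz[:, None] - cz) ** 2 + (yy[None, :] - cy) ** 2
    plane = (dist2 <= r**2) * intensity
    data = np.repeat(plane[:, :, None], shape[2], axis=2)
    return ImageStack(data.astype(float), voxel), (cz, cy), r


@pytest.fixture
def single_path():
    pts = np.column_stack([np.full(20, 12.0), np.full(20, 11.6), np.linspace(1, 22, 20)])
    return VesselPath(0, pts, np.full(20, 4.0))
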