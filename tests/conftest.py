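import numpy as np
import pytest

from sciquant.grid import VolumeGrid
from sciquant.thresholds import CandidateROI


@pytest.fixture
def toy_volumes():
    """A 12^3 grid with a cortex shell at FLAIR/T1 = 100/200 and a
    white-matter core at 80/130, anisotropic 0.65 x 0.65 x 1.0 mm voxels."""
    shape = (12, 12, 12)
    vs = (0.65, 0.65, 1.0)
    flair = np.zeros(shape)
    t1 = np.zeros(shape)
    cortex = np.zeros(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    cortex[1:11, 1:11, 1:11] = True
    wm[3:9, 3:9, 3:9] = True
    cortex &= ~wm
    flair[cortex] = 100.0
    t1[cortex] = 200.0
    flair[wm] = 80.0
    t1[wm] = 130.0
    return VolumeGrid(flair, vs), VolumeGrid(t1, vs), cortex, wm


def box_roi(roi_id, lo, hi, lobe="frontal"):
    """Axis-aligned box ROI from inclusive lower to exclusive upper corner."""
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    voxels = np.stack([g.ravel() for g in grids], axis=1)
    return CandidateROI(roi_id=roi_id, voxels=voxels, lobe=lobe)
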