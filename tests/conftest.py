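import numpy as np
import pytest

from tagfold import synthetic_data as sd
from tagfold.segments import SegmentMap


@pytest.fixture
def ub_segments() -> SegmentMap:
    return SegmentMap()


@pytest.fixture
def toy_segments() -> SegmentMap:
    """Segment map sized for 10-residue synthetic NMR datasets."""
    return SegmentMap({"b1": (1, 3), "a1": (4, 7), "b2": (8, 10)})


@pytest.fixture
def static_toy() -> "sd.Trajectory":
    return sd.gen_toy_trajectory(
        sd.ToyTrajectorySpec(n_residues=16, fluct_amplitudes=0.0, n_frames=4,
                             seed=0))
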