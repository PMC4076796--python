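import numpy as np
import pytest

from fmripitfalls import Blob, DesignSpec, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def block_design():
    """Three 20 s blocks in a 160 s acquisition at TR = 2 s."""
    return DesignSpec(onsets=(20.0, 60.0, 100.0), durations=(20.0, 20.0, 20.0), tr=2.0, n_scans=80)


@pytest.fixture
def small_phantom_spec():
    """24-voxel cube with one radius-3 blob centered in the gray shell."""
    return PhantomSpec(shape=(24, 24, 24), blobs=(Blob(center=(12, 12, 20), radius=3.0, amplitude=1.0),))
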