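import numpy as np
import pytest

from halopose.synthetic import frames_from_targets


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def pose_frame():
    """One synthetic frame with known (d, theta) targets for all channels."""
    return frames_from_targets(
        {1: (8.0, 140.0), 2: (9.0, 120.0), 3: (15.0, 60.0)},
        anchor_targets=(8.5, 11.0),
        seed=11,
    )
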