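import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rosyn.intervals import CoverageTrack


@pytest.fixture
def simple_track() -> CoverageTrack:
    """Two adjacent steps: [0,10)=1, [10,20)=3 on chr1."""
    return CoverageTrack([("chr1", 0, 10, 1.0), ("chr1", 10, 20, 3.0)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
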