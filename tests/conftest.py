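import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from sozloc import Recording, SynthSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """Six channels, one SOZ, eight minutes at 2 kHz — enough for a full

    pipeline run in a few seconds."""
    spec = SynthSpec(
        n_channels=6,
        soz_channels=("CH01",),
        duration_minutes=8.0,
        seed=42,
    )
    return generate_recording(spec)


@pytest.fixture
def toy_recording(rng):
    """Tiny unlabeled-content recording for I/O and segmentation tests."""
    samples = rng.standard_normal((3, 2000 * 45))  # 45 s at 2 kHz
    return Recording(samples, 2000.0, ("A", "B", "C"), frozenset({"B"}))
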