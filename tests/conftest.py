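import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from frustmode.structure import ProteinFrame
from frustmode.synthetic import FoldSpec, build_toy_fold


@pytest.fixture(scope="session")
def small_fold() -> ProteinFrame:
    """Compact 44-residue helix/coil/strand fold used across modules."""
    spec = FoldSpec(segments=(("helix", 12), ("coil", 12), ("strand", 8),
                              ("coil", 12)), seed=7)
    return build_toy_fold(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def two_residue_frame() -> ProteinFrame:
    return ProteinFrame(["A", "L"], np.array([[0.0, 0.0, 0.0], [0.4, 0.0, 0.0]]))
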