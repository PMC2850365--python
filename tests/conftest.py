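import numpy as np
import pytest

from endoforce.core import ChainProbe, PowerLawMedium


@pytest.fixture
def chain2() -> ChainProbe:
    """Default two-endosome chain probe (0.6 µm endosomes, 310 K)."""
    return ChainProbe(2)


@pytest.fixture
def glycerol_probe() -> ChainProbe:
    """Two-bead calibration chain: 1 µm beads, moment 1e-14 A·m², 25 °C."""
    return ChainProbe(2, d_endo=1e-6, moment=1e-14, temperature=298.0)


@pytest.fixture
def intact_medium() -> PowerLawMedium:
    """Intact-cytoskeleton modulus power law."""
    return PowerLawMedium(8.6, 0.40)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
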