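import numpy as np
import pytest

from photoblue.spectral import LogNormalComponent, SpectralBinning


@pytest.fixture
def bins16() -> SpectralBinning:
    return SpectralBinning.default16()


@pytest.fixture
def red_dye() -> LogNormalComponent:
    """A red-emitting dye peaking at 655 nm (STAR-RED-like)."""
    return LogNormalComponent(1000.0, 655.0, 45.0)


@pytest.fixture
def blue_species() -> LogNormalComponent:
    """The photoblued species: 22 nm blue-shifted, slightly narrower."""
    return LogNormalComponent(1000.0, 633.0, 42.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
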