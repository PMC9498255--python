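import numpy as np
import pytest

from modhill import (
    HillClassicParams,
    ModulatedHillParams,
    ODCDataset,
    REFERENCE_FITS,
    hill_classic_saturation,
    modulated_hill_saturation,
)


@pytest.fixture
def winslow_lorentz() -> ModulatedHillParams:
    """Published Lorentz-profile estimates for the Winslow whole-blood curve."""
    return REFERENCE_FITS[("winslow", "lorentz")]


@pytest.fixture
def severinghaus_gauss() -> ModulatedHillParams:
    """Published Gauss-profile estimates for the Severinghaus curve."""
    return REFERENCE_FITS[("severinghaus", "gauss")]


@pytest.fixture
def classic_noiseless() -> tuple:
    """Noiseless classic-Hill dataset with its generating truth."""
    truth = HillClassicParams(27.0, 2.6)
    p = np.geomspace(1.0, 150.0, 25)
    return ODCDataset(p, hill_classic_saturation(p, truth)), truth


@pytest.fixture
def lorentz_noiseless(winslow_lorentz) -> tuple:
    """Noiseless modulated-Hill (Lorentz) dataset with its truth."""
    p = np.geomspace(1.0, 150.0, 25)
    y = modulated_hill_saturation(p, winslow_lorentz)
    return ODCDataset(p, y), winslow_lorentz
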