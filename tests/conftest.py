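import numpy as np
import pytest

from capdet.filterbank import WaveletFilterBank, design_omsbm_filter


@pytest.fixture(scope="session")
def omsbm_bank() -> WaveletFilterBank:
    """The length-12, 4-vanishing-moment, 5-level bank (designed once)."""
    return design_omsbm_filter(12, 4, 5)


@pytest.fixture(scope="session")
def haar_bank() -> WaveletFilterBank:
    return WaveletFilterBank.from_lowpass(
        np.array([1.0, 1.0]) / np.sqrt(2.0), levels=1, name="haar"
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
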