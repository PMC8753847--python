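import numpy as np
import pytest

from airwayphys import synthetic as syn
from airwayphys.calcium import CalibrationConstants


@pytest.fixture(scope="session")
def constants() -> CalibrationConstants:
    """Fura-2 calibration constants of the study."""
    return CalibrationConstants(kd=386.0, rmin=0.5, rmax=11.7, beta=7.5)


@pytest.fixture(scope="session")
def default_train() -> syn.Waveform:
    """Ten identical resting breaths at 200 Hz, noise-free."""
    return syn.gen_breath_train([syn.GUINEA_PIG_BREATH] * 10, sample_rate=200.0, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
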