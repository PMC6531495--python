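import numpy as np
import pytest

from colourgame.stimuli import ChipArray, StimulusSet, synth_stimuli


@pytest.fixture(scope="session")
def clustered_stimuli() -> StimulusSet:
    """The desk-scale clustered stimulus set used across the suite."""
    return synth_stimuli(300, 6, 0.3, seed=1)


@pytest.fixture(scope="session")
def synthetic_array() -> ChipArray:
    return ChipArray.synthetic(seed=0)


@pytest.fixture()
def two_stimuli() -> StimulusSet:
    """Two well-separated stimuli for minimal-game tests."""
    return StimulusSet(np.array([[30.0, 0.0, 0.0], [70.0, 40.0, 10.0]]), label="synthetic")
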