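import numpy as np
import pytest

from somnoval.core import Hypnogram
from somnoval.synthio import gen_night


@pytest.fixture(scope="session")
def small_night():
    """One four-hour synthetic night with default (noisy) confusion."""
    return gen_night("fixture", seed=20210, n_psg_epochs=720)


@pytest.fixture(scope="session")
def clean_night():
    """Noise-free night: identity confusion, zero offset, block-aligned
    stage changes."""
    return gen_night("fixture-clean", seed=20211, n_psg_epochs=720,
                     confusion=np.eye(4), min_run_epochs=1, clock_offset=0.0,
                     stage_block_s=60.0)


@pytest.fixture()
def worked_hypnogram():
    """The seven-epoch PSG example used for hand enumeration."""
    return Hypnogram(0.0, 20.0, np.array(["W", "N1", "N2", "N2", "W", "REM", "W"],
                                         dtype=object))
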