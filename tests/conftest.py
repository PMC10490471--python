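import numpy as np
import pytest

from phasicvns.design import StudyDesign, EffectSpec


@pytest.fixture
def tiny_design():
    """Two subjects, one EST block, few PLRT trials: fast end-to-end runs."""
    return StudyDesign(n_subjects=2, n_blocks_est=1, n_trials_plrt=4)


@pytest.fixture
def default_effects():
    return EffectSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
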