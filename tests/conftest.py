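import numpy as np
import pytest

import apri


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    return apri.default_axis(200, 400, 1800)


@pytest.fixture
def small_dataset(small_axis):
    """5×8 grid, mild contamination — fast input for pipeline-level tests."""
    ds, truth = apri.generate_imaging_dataset(
        5, 8, axis=small_axis, seed=11, spike_rate=0.1,
    )
    return ds, truth
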