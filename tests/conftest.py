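import numpy as np
import pytest

import hearloc as hl


@pytest.fixture(scope="session")
def fb30():
    """The standard 30-channel filterbank (300 Hz - 12 kHz, 1 ERB)."""
    return hl.make_filterbank(300.0, 12000.0, 1.0)


@pytest.fixture(scope="session")
def grid200():
    """A small decoding grid: 200 uniform directions above -45 deg elevation."""
    return hl.filter_grid(hl.uniform_sphere_grid(200), -45.0)


@pytest.fixture(scope="session")
def hrtf200(grid200, fb30):
    return hl.synth_hrtf(grid200, seed=11, fb=fb30)


@pytest.fixture(scope="session")
def eco_prior(fb30):
    """Synthetic 'ecological' prior with corpus-like covariance structure."""
    frames = hl.synth_corpus(fb30, 20000, seed=0)
    return hl.build_prior(frames, provenance="synthetic", fb=fb30)


@pytest.fixture(scope="session")
def grid2000():
    return hl.filter_grid(hl.uniform_sphere_grid(2000), -45.0)
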