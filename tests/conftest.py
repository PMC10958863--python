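import numpy as np
import pytest

from grscreen import datagen


@pytest.fixture(scope="session")
def tiny_design():
    """3 lines, anchor + 2 library drugs, single replicate: cheap but full."""
    return datagen.ScreenDesign(
        lines=(("L1", "normal"), ("L2", "tumor"), ("L3", "tumor")),
        drugs=("anchor", "libA", "libB"),
        replicates=1,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_design):
    return datagen.default_truth(tiny_design, seed=11)


@pytest.fixture(scope="session")
def clean_truth(tiny_design):
    """Noise-free, outlier-free truth for exact recovery checks."""
    return datagen.default_truth(tiny_design, seed=11, noise_sd=0.0, outlier_rate=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
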