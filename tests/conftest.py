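import numpy as np
import pytest

from fermgan import (
    GanConfig,
    TabularGAN,
    generate_design,
)
from fermgan.design import DesignRanges, SurfaceCoeffs


@pytest.fixture(scope="session")
def design20():
    """The default 20-run emulated experimental campaign."""
    return generate_design()


@pytest.fixture(scope="session")
def design80():
    """A larger 80-run campaign for model-fitting tests."""
    return generate_design(DesignRanges(n_runs=80, seed=11), SurfaceCoeffs())


@pytest.fixture(scope="session")
def gan_short(design20):
    """A short adversarial run (600 iterations) for structural tests."""
    return TabularGAN(design20, GanConfig(n_iterations=600, eval_every=20, seed=1)).fit()


@pytest.fixture(scope="session")
def synthetic200(gan_short):
    return gan_short.synthesize(seed=2)
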