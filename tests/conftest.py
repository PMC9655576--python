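import numpy as np
import pytest

from trophallaxis.config import default_config
from trophallaxis.heterogeneity import AlphaDistributionSpec, AlphaKind
from trophallaxis.model_core import GlobalParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(regime="TEC", distribution="exponential", *, n_ants=20, n_steps=600,
                 alpha=0.005, forager_multiplier=10.0, **param_overrides):
    """A quick-running colony with a deterministic, fairly active leaving rate."""
    params = GlobalParams(n_ants=n_ants, n_steps=n_steps, **param_overrides)
    aspec = AlphaDistributionSpec(kind=AlphaKind.DELTA, min_value=alpha, max_value=alpha,
                                  forager_multiplier=forager_multiplier)
    return default_config(regime, distribution, params=params, alpha_spec=aspec)


@pytest.fixture
def fast_config():
    return small_config()
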