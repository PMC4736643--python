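import numpy as np
import pytest

from retfit import (CensoredSample, RetentionDistribution, default_scheme,
                    simulate_censored)

# one probe distribution per family, shapes typical of gut retention times
PROBE_DISTS = [
    RetentionDistribution("lognormal", 1.8, 0.6),
    RetentionDistribution("gamma", 2.5, 0.5),
    RetentionDistribution("weibull", 1.8, 9.0),
]


@pytest.fixture
def lognormal_default():
    return RetentionDistribution("lognormal", 1.8, 0.6)


@pytest.fixture(params=PROBE_DISTS, ids=lambda d: d.family)
def probe_dist(request):
    return request.param


@pytest.fixture
def small_sample():
    """Tiny hand-checkable censored sample: intervals (0,1]:2, (1,2]:1."""
    return CensoredSample(lower=[0.0, 1.0], upper=[1.0, 2.0], counts=[2, 1])


@pytest.fixture
def typical_sample(lognormal_default):
    """A typical feeding-trial sample: N=500, mixed 1 h/4 h scheme."""
    return simulate_censored(lognormal_default, 500, default_scheme(), seed=42)
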