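import numpy as np
import pytest

import binmix as bm


@pytest.fixture(scope="session")
def gamma_counts_5k() -> bm.CountVector:
    """Counts from a single gamma mixing distribution (NB marginal), n=5000."""
    return bm.simulate_counts(bm.MixingSpec.gamma(shape=2.0, rate=0.5), 5000, seed=3)


@pytest.fixture(scope="session")
def nbnb_counts_50k() -> bm.CountVector:
    """Heavy-tailed counts: bulk NB(mu=2, r=10) plus 5% tail NB(mu=30, r=0.8)."""
    spec = bm.MixingSpec.gamma_gamma(0.05, shape1=10.0, rate1=5.0, shape2=0.8, rate2=0.8 / 30.0)
    return bm.simulate_counts(spec, 50_000, seed=17)


@pytest.fixture(scope="session")
def nbnb_fit_50k(nbnb_counts_50k) -> bm.FitResult:
    return bm.fit_nbnb(nbnb_counts_50k, seed=0)
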