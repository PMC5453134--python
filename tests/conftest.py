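import numpy as np
import pytest

from mullinsmix import (
    FiberParams,
    IsotropicParams,
    MaterialParams,
    PseudoElasticParams,
    SofteningParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20140116)


@pytest.fixture
def rubber_iso():
    """Vulcanized natural rubber matrix block (energy-split validation set)."""
    return IsotropicParams(mu=0.475, N=28.13, c=-0.188e-6)


@pytest.fixture
def soft_tissue_params():
    """A generic tissue-like composite set, comfortably away from locking."""
    return MaterialParams(
        iso=IsotropicParams(mu=0.95, N=3.25),
        fib=FiberParams(f=0.1, A1=0.5, A2=2.0),
        soft=SofteningParams(b=1.5, C=0.5),
        pe=PseudoElasticParams(m1=0.5, r1=1.5, r2=0.8, gamma=0.5),
    )


def random_iso(rng, mu_range=(0.05, 5.0), n_range=(1.5, 30.0)):
    return IsotropicParams(
        mu=float(rng.uniform(*mu_range)), N=float(rng.uniform(*n_range))
    )
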