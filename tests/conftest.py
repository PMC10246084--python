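import numpy as np
import pytest

from lrpop import (Domain, DispersalSpec, KernelSpec, logistic_demography,
                   neutral_demography, pme_demography, poisson_uniform)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def domain1d():
    return Domain(1, (10.0,), "periodic")


@pytest.fixture
def small_logistic():
    """Logistic preset on a short periodic habitat, cheap enough for
    replicated event-driven runs."""
    theta, N = 5.0, 50.0
    dom = Domain(1, (1.0,), "periodic")
    dem = logistic_demography(theta, N, kernel_scale=0.3)
    disp = DispersalSpec(theta=theta, dim=1, sigma2=1.0)
    return dem, disp, dom


@pytest.fixture
def gauss_kernel():
    return KernelSpec("gaussian", 1.0, 1)
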