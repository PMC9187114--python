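import numpy as np
import pandas as pd
import pytest

from itcvigour.cohort import default_truth, simulate_cohort
from itcvigour.design import DesignSpec, build_design
from itcvigour.sampler import MCMCConfig


@pytest.fixture(scope="session")
def small_design():
    """Reduced grid: 2 conditions x 2 ratios x 3 delays = 12 trials."""
    return DesignSpec(ss_amounts=(10.0, 20.0), ratios=(1.5, 3.8), delays=(1, 31, 122))


@pytest.fixture(scope="session")
def default_trials():
    return build_design()


@pytest.fixture(scope="session")
def short_cfg():
    return MCMCConfig(n_chains=2, burn_in=300, n_samples=400, seed=9)


@pytest.fixture(scope="session")
def softmax_cohort_small():
    """8-subject softmax cohort used by several estimation tests."""
    return simulate_cohort(default_truth("softmax-absolute"), 8, seed=31)


@pytest.fixture(scope="session")
def ddm_cohort_small():
    """6-subject sigmoid-DDM cohort with vigour columns."""
    return simulate_cohort(default_truth("ddm-sig-absolute"), 6, seed=32, with_vigour=True)
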