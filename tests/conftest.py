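import warnings

import numpy as np
import pytest

from divehrv.pipeline import analysis_frame
from divehrv.synth import simulate_cohort

# mixed-model boundary warnings are expected on small synthetic cohorts
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort at the RR level, shared across analysis tests."""
    return simulate_cohort(n_subjects=12, seed=7)


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    """Feature + impairment analysis frame for the shared cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analysis_frame(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
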