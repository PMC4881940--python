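import numpy as np
import pytest

from twinstage import CholeskyACEParams, MeanTrajectory, design, simulate_cohort


def univariate_params(a2: float, c2: float, e2: float) -> CholeskyACEParams:
    """Single-stage loadings from standardized variance proportions."""
    return CholeskyACEParams(
        np.array([[np.sqrt(a2)]]), np.array([[np.sqrt(c2)]]), np.array([[np.sqrt(e2)]])
    )


@pytest.fixture(scope="session")
def wellbeing_params():
    return design.default_params("wellbeing")


@pytest.fixture(scope="session")
def mentalhealth_params():
    return design.default_params("mentalhealth")


@pytest.fixture(scope="session")
def small_cohort(wellbeing_params):
    """A design-sized cohort (167 MZ + 208 DZ pairs) with the default trajectory."""
    return simulate_cohort(
        design.N_MZ_PAIRS,
        design.N_DZ_PAIRS,
        wellbeing_params,
        design.default_trajectory(),
        seed=42,
    )
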