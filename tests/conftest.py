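from datetime import date

import numpy as np
import pytest

from haircort import CohortParams, HairSeries, fit_cohort, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortParams(rng_seed=1))


@pytest.fixture(scope="session")
def default_fits(default_cohort):
    return fit_cohort(default_cohort)


@pytest.fixture
def clean_exponential_series():
    """Noiseless 10 * exp(-2.2 t) over six 2-cm segments."""
    t = (np.arange(1, 7) - 0.5) * 2 / 12.0
    return HairSeries("clean", date(2020, 6, 1), 10.0 * np.exp(-2.2 * t))


def white_cohort_params(seed: int, n: int = 55) -> CohortParams:
    """Featureless cohort: white fluctuations + assay noise + decline,
    no seasonal component."""
    return CohortParams(n_participants=n, seasonal_amplitude=0.0,
                        fluctuation_spectrum="white", rng_seed=seed)
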