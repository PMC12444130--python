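import numpy as np
import pytest

from biliwash import BilirubinSeries, CohortConfig, ExchangeParams, standard_rate

# Cohort-mean decline curve observed every 30 min during a 120-min
# single-volume-per-hour exchange (μmol/L).
OBSERVED_MEAN = BilirubinSeries(
    np.array([0.0, 30.0, 60.0, 90.0, 120.0]),
    np.array([498.1, 378.5, 278.4, 234.6, 216.7]),
    "observed",
)


@pytest.fixture
def observed_mean_series() -> BilirubinSeries:
    return OBSERVED_MEAN


@pytest.fixture
def standard_params() -> ExchangeParams:
    """Standardized double-volume/120-min exchange for a 282 mL pool."""
    return ExchangeParams(282.0, standard_rate(282.0), 120.0)


@pytest.fixture
def small_cohort_config() -> CohortConfig:
    return CohortConfig(n_patients=6, seed=7)
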