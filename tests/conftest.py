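import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from tmtquant.simulate import CohortConfig, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete 3-plex cohort with contamination, low-quality
    PSMs and missingness."""
    return generate_cohort(CohortConfig(n_proteins=60, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: no PSM noise, batch shifts, missingness or junk."""
    cfg = CohortConfig(
        n_proteins=30, seed=5, psm_noise_sd=0.0, batch_shift_sd=0.0,
        bio_sd=0.2, missing_rates=(0.0, 0.0, 0.0),
        lowquality_fraction=0.0, contaminant_fraction=0.0,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(42)
    m = pd.DataFrame(rng.normal(25, 1, (30, 8)),
                     index=[f"G{i:02d}" for i in range(30)],
                     columns=[f"s{j}" for j in range(8)])
    return m
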