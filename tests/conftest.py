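import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mnhcov as m

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid33():
    return m.synthetic_district_grid(3, 3)


@pytest.fixture(scope="session")
def structure33(grid33):
    return m.icar_precision(grid33)


@pytest.fixture(scope="session")
def small_survey(grid33):
    """A 3x3-grid survey with known truth (576 women)."""
    truth = m.realize_truth(grid33, m.DEFAULT_BETA, sigma_b=0.8, phi=0.6, seed=41)
    clusters = m.generate_clusters(grid33, clusters_per_district=8, urban_fraction=0.3, seed=42)
    survey, truth = m.generate_survey(grid33, clusters, women_per_cluster=8, truth=truth, seed=43)
    return m.recode_survey(survey), truth


@pytest.fixture(scope="session")
def small_fit(small_survey, structure33):
    """One short-chain fit on the small survey, shared across test modules."""
    data, _ = small_survey
    return m.fit(
        m.ModelSpec("sba"),
        data,
        structure33,
        m.McmcSettings(chains=2, iters=800, warmup=300, seed=7),
    )
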