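import numpy as np
import pandas as pd
import pytest

from lagerscale import (
    DEFAULT_HIERARCHY,
    PipelineConfig,
    RatingsTable,
    SurveyConfig,
    generate_survey,
)


@pytest.fixture(scope="session")
def hierarchy():
    return DEFAULT_HIERARCHY


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(seed=42)


@pytest.fixture(scope="session")
def small_survey(hierarchy):
    """A reproducible 120-respondent synthetic survey."""
    return generate_survey(
        SurveyConfig(n_respondents=120, hierarchy=hierarchy, seed=7)
    )


@pytest.fixture()
def tiny_ratings(hierarchy):
    """Three respondents with fully specified ratings (no randomness)."""
    rng = np.random.default_rng(3)
    data = {
        "respondent_id": ["r1", "r2", "r3", "r4"],
        "cohort": ["low", "low", "mid", "high"],
    }
    for a in hierarchy.attributes:
        data[a] = rng.integers(1, 6, size=4)
    return RatingsTable(data=pd.DataFrame(data), hierarchy=hierarchy)
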