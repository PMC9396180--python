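
import pandas as pd
import pytest

from gai import (ModelConfig, SiteTotalSpec, TruthConfig, fit_gai,
                 simulate_survey)


@pytest.fixture
def tiny_long_df():
    """2 sites x 3 occasions, counts 0..5, with a site-level covariate."""
    return pd.DataFrame({
        "site": ["A", "A", "A", "B", "B", "B"],
        "occasion": [1, 2, 3, 1, 2, 3],
        "count": [0, 1, 2, 3, 4, 5],
        "northing": [100.0] * 3 + [700.0] * 3,
    })


@pytest.fixture(scope="session")
def univoltine_truth():
    return TruthConfig(S=30, T=26, family="mixture", B=1, mu=(13.0,),
                       sigma=(2.5,), w=(1.0,),
                       site_total=SiteTotalSpec("constant", 200.0), seed=42)


@pytest.fixture(scope="session")
def univoltine_survey(univoltine_truth):
    data, record = simulate_survey(univoltine_truth)
    return data, record


@pytest.fixture(scope="session")
def univoltine_fit(univoltine_survey):
    data, _ = univoltine_survey
    return fit_gai(data, ModelConfig(family="mixture", B=1))
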