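import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20180501)


@pytest.fixture
def red_records():
    """Four equally weighted people at 30, 100, 100 and 300 g/day red meat."""
    return pd.DataFrame(
        {
            "person_id": ["a", "b", "c", "d"],
            "sex": "male",
            "red_g_day": [30.0, 100.0, 100.0, 300.0],
            "processed_g_day": [0.0, 20.0, 60.0, 200.0],
            "weight": 1.0,
        }
    )


@pytest.fixture
def survey_records():
    """A moderate synthetic survey block for pipeline-level tests."""
    from meatcost import synthetic_data as sd

    params = sd.default_survey_params("2017-2018", "male", n_records=3000)
    return sd.generate_survey(params, seed=7)
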