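import numpy as np
import pandas as pd
import pytest

from caseonly.simdata import ScenarioConfig, generate_cohort


@pytest.fixture
def six_subject_cohort():
    """Hand-checkable cohort: times {1,2,3,4,5,5}, alternating arms,
    events at t = 1, 2, 3."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5, 6],
            "M": [1, 0, 1, 0, 1, 0],
            "T": [1, 0, 1, 0, 1, 0],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 5.0],
            "event": [1, 1, 1, 0, 0, 0],
        }
    )


@pytest.fixture
def large_null_cohort():
    """10^5 subjects, no covariate effects, no random censoring."""
    config = ScenarioConfig(
        n=100_000, hr_M=1.0, hr_T=1.0, hr_I=1.0, q_c=0.0, seed=11
    )
    return generate_cohort(config, np.random.default_rng(11)), config
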