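import numpy as np
import pandas as pd
import pytest

from phenoclust.io import CATEGORICAL, CONTINUOUS, CohortTable, VariableMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Six subjects, two continuous + one categorical variable, one missing cell."""
    values = pd.DataFrame(
        {
            "bmi": [22.0, 30.5, np.nan, 27.0, 24.2, 35.1],
            "age": [44.0, 61.0, 52.0, 38.0, 70.0, 55.0],
            "eye": ["blue", "brown", "green", "blue", np.nan, "brown"],
        },
        index=[f"s{i}" for i in range(6)],
    )
    meta = [
        VariableMeta("bmi", CONTINUOUS, "clinical", control_mean=25.0, control_sd=4.0),
        VariableMeta("age", CONTINUOUS, "demographics", control_mean=50.0, control_sd=10.0),
        VariableMeta("eye", CATEGORICAL, "demographics",
                     control_freq={"blue": 0.3, "brown": 0.5, "green": 0.2}),
    ]
    return CohortTable(values, meta)


def ideal_block_matrix(sizes):
    """Similarity matrix with 1 inside blocks and 0 between (diagonal 1)."""
    labels = np.concatenate([[k + 1] * s for k, s in enumerate(sizes)])
    M = (labels[:, None] == labels[None, :]).astype(float)
    return M, labels


@pytest.fixture
def blocks_3x4():
    return ideal_block_matrix([4, 4, 4])
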