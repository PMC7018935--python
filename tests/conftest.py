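import numpy as np
import pandas as pd
import pytest

from coldeval import IndexMatrix, load_physiological_example
from coldeval.containers import HIGHER_IS_BETTER, LOWER_IS_BETTER


@pytest.fixture(scope="session")
def worked_example():
    return load_physiological_example()


@pytest.fixture()
def random_index_matrix():
    """20 varieties × 5 correlated indices with mixed polarity."""
    rng = np.random.default_rng(42)
    t = rng.uniform(0, 1, 20)
    df = pd.DataFrame(
        {
            "LWD7": 9 - 8 * t + rng.normal(0, 0.4, 20),
            "RLWD7": 9 - 8 * t + rng.normal(0, 0.4, 20),
            "SR": 0.1 + 0.9 * t + rng.normal(0, 0.05, 20),
            "CRI": 0.3 + 0.7 * t + rng.normal(0, 0.05, 20),
            "NRI": 0.3 + 0.7 * t + rng.normal(0, 0.05, 20),
        },
        index=[f"V{i:02d}" for i in range(20)],
    )
    polarity = {
        "LWD7": LOWER_IS_BETTER,
        "RLWD7": LOWER_IS_BETTER,
        "SR": HIGHER_IS_BETTER,
        "CRI": HIGHER_IS_BETTER,
        "NRI": HIGHER_IS_BETTER,
    }
    return IndexMatrix(df, polarity)
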