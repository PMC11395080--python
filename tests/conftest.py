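import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from treghub.diffexpr import CountMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes x 4 samples, all-positive, hand-checkable."""
    counts = pd.DataFrame(
        {
            "s1": [10, 20, 30],
            "s2": [20, 40, 60],
            "s3": [10, 20, 30],
            "s4": [10, 20, 30],
        },
        index=["g1", "g2", "g3"],
    )
    groups = pd.Series(
        {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
    )
    return CountMatrix(counts=counts, groups=groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240828)
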