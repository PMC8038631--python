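import numpy as np
import pandas as pd
import pytest

import muacglm as mg


@pytest.fixture(scope="session")
def cohort163() -> mg.CohortTable:
    """A default synthetic cohort of the reference study's size."""
    return mg.generate(mg.default_config(163, seed=42))


@pytest.fixture(scope="session")
def cohort5000() -> mg.CohortTable:
    """A larger default synthetic cohort for recovery-style checks."""
    return mg.generate(mg.default_config(5000, seed=11))


@pytest.fixture()
def toy_frame() -> pd.DataFrame:
    """Tiny hand-checkable covariate frame."""
    return pd.DataFrame(
        {
            "weight": [1.0, 2.0, 3.0],
            "height": [10.0, 10.0, 20.0],
            "age": [1.0, 2.0, 3.0],
        }
    )


def make_cohort_frame(n: int, seed: int) -> pd.DataFrame:
    """Small positive random frame with all cohort columns."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.uniform(0.2, 5.0, n),
            "weight": rng.uniform(2.0, 20.0, n),
            "height": rng.uniform(45.0, 120.0, n),
            "hemoglobin": rng.uniform(5.0, 15.0, n),
            "protein": rng.uniform(50.0, 84.0, n),
            "albumen": rng.uniform(22.0, 48.0, n),
            "muac": rng.uniform(8.0, 18.0, n),
        }
    )
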