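import numpy as np
import pandas as pd
import pytest

from methage.meth_io import BetaMatrix


@pytest.fixture
def tiny_matrix() -> BetaMatrix:
    """3 probes x 2 samples, hand-checkable values."""
    df = pd.DataFrame(
        [[0.1, 0.2], [0.5, 0.6], [0.9, 0.8]],
        index=["cg000001", "cg000002", "cg000003"],
        columns=["S1", "S2"],
    )
    return BetaMatrix(df)


@pytest.fixture
def tiny_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S2"],
            "age": [25.0, 30.9],
            "age_is_integer": [True, False],
            "sex": ["male", "female"],
            "cohort": ["control", "case"],
            "study_id": ["STUDY00", "STUDY00"],
            "bmi": [22.5, 27.1],
        }
    )


def make_matrix(values: np.ndarray, prefix: str = "cg") -> BetaMatrix:
    p, n = values.shape
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i:06d}" for i in range(p)],
            columns=[f"S{i:04d}" for i in range(n)],
        )
    )
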