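import numpy as np
import pandas as pd
import pytest

from scoliomir.epi_screen import ScreeningRecord
from scoliomir.smallrna_quant import CountMatrix


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """Tiny hand-checkable count matrix: one pair, three miRNAs."""
    raw = pd.DataFrame(
        {"AIS_1": [40, 19, 10], "CTRL_1": [10, 10, 10]},
        index=["mir-a", "mir-b", "mir-c"],
    )
    libs = pd.Series({"AIS_1": 1_000_000, "CTRL_1": 1_000_000})
    return CountMatrix(raw, libs)


def make_record(subject_id="S1", age=12, sex="female", **kwargs) -> ScreeningRecord:
    return ScreeningRecord(subject_id=subject_id, age=age, sex=sex, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240424)
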