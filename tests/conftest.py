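import numpy as np
import pandas as pd
import pytest

from profuse.data_model import CohortTable, ModalityPartition, VariableSpec


@pytest.fixture
def two_block_partition():
    return ModalityPartition(
        (("basic", ("sex", "age")), ("labs", ("hb", "crp"))), fixed_prefix=1
    )


@pytest.fixture
def small_table():
    """Six samples, two blocks, one sample missing each block."""
    idx = pd.Index([f"s{i}" for i in range(6)], name="sample_id")
    values = pd.DataFrame(
        {
            "sex": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0],
            "age": [70.0, 81.0, 65.0, 90.0, 77.0, 84.0],
            "hb": [120.0, 98.0, np.nan, 131.0, 105.0, 140.0],
            "crp": [3.0, 11.0, np.nan, 2.0, 8.0, 1.0],
        },
        index=idx,
    )
    outcome = pd.Series([0, 1, 0, 1, 1, 0], index=idx, name="outcome")
    variables = [
        VariableSpec("sex", "binary"),
        VariableSpec("age", "continuous", unit="years"),
        VariableSpec("hb", "continuous", unit="g/L"),
        VariableSpec("crp", "continuous"),
    ]
    return CohortTable(values=values, outcome=outcome, variables=variables)
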