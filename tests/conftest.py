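import numpy as np
import pandas as pd
import pytest

from zinbda.table_io import CountTable, SampleMetadata


@pytest.fixture
def toy_table():
    # counts ((1,2),(3,4)): depths are the column sums (4, 6)
    return CountTable(np.array([[1, 2], [3, 4]]), ["f1", "f2"], ["s1", "s2"])


@pytest.fixture
def toy_metadata(toy_table):
    return SampleMetadata(pd.DataFrame({
        "sample_id": toy_table.sample_ids,
        "diet": ["A", "B"],
        "cage": ["c1", "c2"],
    }))


def make_metadata(sample_ids, diets, cages):
    return SampleMetadata(pd.DataFrame({
        "sample_id": list(sample_ids), "diet": list(diets), "cage": list(cages)}))
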