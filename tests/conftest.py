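import datetime

import numpy as np
import pandas as pd
import pytest

from indirect_ri.data_model import COLUMNS, Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(rows, source="lis"):
    """Build a Dataset from (subject_id, date, age, sex, analyte, value) tuples."""
    df = pd.DataFrame(
        [(sid, d if isinstance(d, datetime.date) else datetime.date.fromisoformat(d),
          age, sex, analyte, value, "", source)
         for sid, d, age, sex, analyte, value in rows],
        columns=COLUMNS,
    )
    return Dataset(df)


@pytest.fixture
def tiny_dataset():
    return make_dataset([
        ("A", "2017-03-01", 4.2, "male", "creatinine", 30.0),
        ("A", "2017-08-01", 4.6, "male", "creatinine", 33.0),
        ("B", "2017-05-10", 8.0, "female", "creatinine", 41.0),
        ("B", "2017-05-10", 8.0, "female", "urea", 4.4),
        ("C", "2017-01-20", 14.5, "male", "creatinine", 62.0),
    ])
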