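import numpy as np
import pandas as pd
import pytest

import tidymat as tm


@pytest.fixture
def small():
    """3x2 container mirroring the running RNA-seq example."""
    return tm.make_annotated_matrix(
        assays={"counts": np.array([[2, 4], [6, 8], [1, 3]])},
        row_data={"length": [100, 5000, 200]},
        col_data={"grp": ["a", "b"], "lib_size": [5.0, 15.0]},
        row_names=["g1", "g2", "g3"],
        col_names=["s1", "s2"],
    )


@pytest.fixture
def square22():
    return tm.make_annotated_matrix(
        assays={"counts": np.array([[1, 2], [3, 4]])},
        row_data={"len": [10, 20]},
        col_data={"grp": ["a", "b"]},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
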