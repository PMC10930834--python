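import numpy as np
import pandas as pd
import pytest

import broilerdea as bd


@pytest.fixture(scope="session")
def broiler():
    """The packaged 31-batch dataset."""
    return bd.load_broiler31()


@pytest.fixture(scope="session")
def broiler_crs_input(broiler):
    return bd.scores(broiler, bd.ModelSpec("crs", "input"))


def make_table(X, Y, ids=None):
    """Build a generic DMUTable from input/output arrays."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    in_names = tuple(f"x{j+1}" for j in range(X.shape[1]))
    out_names = tuple(f"y{i+1}" for i in range(Y.shape[1]))
    frame = pd.DataFrame(
        np.hstack([X, Y]),
        columns=list(in_names) + list(out_names),
        index=pd.Index(ids or range(1, len(X) + 1), name="dmu"),
    )
    return bd.DMUTable(frame=frame, input_names=in_names, output_names=out_names)
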