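import numpy as np
import pandas as pd
import pytest

from somnomet import MetaboliteTable


def make_table(values, states, protocols=None, sample_ids=None, metabolite_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    metabolite_ids = metabolite_ids or [f"M{j + 1:04d}" for j in range(p)]
    protocols = protocols or ["none"] * n
    ann = pd.DataFrame(
        {"state": states, "protocol": protocols, "zt": [5.2] * n},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return MetaboliteTable(sample_ids, metabolite_ids, values, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table(rng):
    """6 samples (3 REM / 3 Wake) x 4 metabolites, strictly positive."""
    values = rng.lognormal(mean=3.0, sigma=0.3, size=(6, 4))
    return make_table(values, ["REM"] * 3 + ["Wake"] * 3)
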