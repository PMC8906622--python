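import numpy as np
import pandas as pd
import pytest

from omivec.model import ConditionKey, FeatureTable
from omivec.simulate import default_study


def make_table(values, layer="transcript", conditions=None, sample_ids=None,
               feature_ids=None):
    """Build a small FeatureTable from a 2D array and per-sample conditions."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j + 1}" for j in range(p)]
    conditions = conditions or [ConditionKey("C57BL/6", 0, "control")] * n
    meta = pd.DataFrame(
        {"strain": [c.strain for c in conditions],
         "day": [c.day for c in conditions],
         "arm": [c.arm for c in conditions]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return FeatureTable(
        values=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        layer=layer,
        metadata=meta,
    )


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study, one fixed seed, shared across tests."""
    return default_study(seed=11)


@pytest.fixture
def two_group_conditions():
    a = ConditionKey("C57BL/6", 0, "control")
    b = ConditionKey("C57BL/6", 7, "treated")
    return a, b
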