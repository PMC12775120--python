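import numpy as np
import pandas as pd
import pytest

import sbspca
from sbspca import FeatureTable, GeneratorConfig


IS_IDS = [f"IS{i + 1:02d}" for i in range(5)]


@pytest.fixture(scope="session")
def dataset_ii():
    """Default daily-sample emulation: 52 time points, 9 spiked targets."""
    return sbspca.generate_dataset(GeneratorConfig(seed=11), "II")


def make_table(X, mz=None, rt=None, ids=None):
    """Small helper: wrap a raw matrix into a FeatureTable."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    ids = ids or [f"f{j + 1:03d}" for j in range(p)]
    feature_meta = pd.DataFrame(
        {
            "feature_id": ids,
            "mz": mz if mz is not None else np.linspace(100, 500, p),
            "rt": rt if rt is not None else np.linspace(1, 10, p),
        }
    )
    sample_meta = pd.DataFrame(
        {"time_index": np.arange(1, n + 1), "label": [f"t{i + 1:03d}" for i in range(n)]}
    )
    return FeatureTable(X=X, feature_meta=feature_meta, sample_meta=sample_meta)
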