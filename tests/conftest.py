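import numpy as np
import pandas as pd
import pytest

from organnet import SUVTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, organs=None, groups=None, prefix="scan"):
    """Small SUVTable from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    organs = organs or [f"organ{i}" for i in range(k)]
    scan_ids = [f"{prefix}{i}" for i in range(n)]
    groups = pd.Series(groups or ["ref"] * n, index=scan_ids)
    return SUVTable(pd.DataFrame(values, index=scan_ids, columns=organs), groups)


@pytest.fixture
def small_table(rng):
    """5 scans x 4 organs of positive random SUVs, all labelled 'ref'."""
    return make_table(rng.uniform(0.5, 3.0, size=(5, 4)))


def pearson_oracle(x, y):
    """Direct-formula Pearson correlation, independent of numpy.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
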