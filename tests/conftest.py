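import numpy as np
import pandas as pd
import pytest

from catechoflux import SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(intensities, doses, times, donors, features=None):
    """Assemble a SampleTable from parallel per-sample lists."""
    n = len(intensities)
    assert len(doses) == len(times) == len(donors) == n
    intens = np.asarray(intensities, dtype=float)
    if features is None:
        features = [f"F{i}" for i in range(intens.shape[1])]
    index = pd.Index([f"s{i}" for i in range(n)], name="sample")
    meta = pd.DataFrame(
        {
            "dose_uM": doses,
            "time_h": times,
            "donor": donors,
            "batch": donors,
        },
        index=index,
    )
    return SampleTable(pd.DataFrame(intens, index=index, columns=features), meta)


@pytest.fixture
def small_table():
    """2 features x (2 doses x 2 times x 1 donor), exact powers of two."""
    # F0 responds 4-fold at dose 5 both times; F1 flat
    rows = [
        [100.0, 50.0],  # dose 0, t 4
        [400.0, 50.0],  # dose 5, t 4
        [100.0, 50.0],  # dose 0, t 24
        [400.0, 50.0],  # dose 5, t 24
    ]
    return make_table(
        rows,
        doses=[0.0, 5.0, 0.0, 5.0],
        times=[4.0, 4.0, 24.0, 24.0],
        donors=["d1"] * 4,
    )
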