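import numpy as np
import pytest

from iccbias import MeasurementTable


@pytest.fixture
def toy_table() -> MeasurementTable:
    """Three clusters of two observations: {(1,2), (3,5), (9,7)}."""
    return MeasurementTable.from_records(
        [("A", 1.0), ("A", 2.0), ("B", 3.0), ("B", 5.0), ("C", 9.0), ("C", 7.0)]
    )


@pytest.fixture
def random_table() -> MeasurementTable:
    """A moderately sized balanced dataset with interleaved cluster rows."""
    rng = np.random.default_rng(1234)
    n, k = 12, 5
    y = rng.normal(50.0, 4.0, size=n) [:, None] + rng.normal(0.0, 2.0, size=(n, k))
    ids = np.repeat([f"c{i:02d}" for i in range(n)], k)
    perm = rng.permutation(n * k)
    return MeasurementTable(ids[perm], y.ravel()[perm])
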