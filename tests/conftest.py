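import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scalemorph as sm
from scalemorph.data_io import MeasurementTable, ScaleRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(X, variables, ids=None) -> MeasurementTable:
    """Build a MeasurementTable from an (n, p) array."""
    X = np.asarray(X, dtype=float)
    ids = ids or [f"s{i:03d}" for i in range(X.shape[0])]
    records = [
        ScaleRecord(scale_id=sid, lengths=dict(zip(variables, map(float, row))))
        for sid, row in zip(ids, X)
    ]
    return MeasurementTable(records=records, variable_names=tuple(variables))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def default_sample():
    """One default synthetic study-condition sample (226 scales, 8 clusters)."""
    return sm.generate_measurements(sm.default_reference_spec(), seed=7)


@pytest.fixture
def two_blob_table():
    """Two tight, far-separated 3-point blobs in 2 variables."""
    pts = [
        [0.0, 0.0], [0.1, 0.0], [0.0, 0.1],
        [10.0, 10.0], [10.1, 10.0], [10.0, 10.1],
    ]
    return make_table(pts, ("L5", "L6"))
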