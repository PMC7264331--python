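import numpy as np
import pytest

from hrvnet.markers import marker_table
from hrvnet.rr import RRSeries
from hrvnet.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort100():
    """100 synthetic patients, 1000 beats each, spanning every class."""
    counts = {"H": 21, "AF": 20, "CD": 8, "DIAB": 6, "TIR": 8, "TENS": 4, "O": 33}
    return generate_cohort(CohortConfig(class_counts=counts, series_length=1000, seed=42))


@pytest.fixture(scope="session")
def markers100(cohort100):
    """49-marker table of the 100-patient cohort."""
    return marker_table(cohort100)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_series(values, label="unknown", patient_id="t"):
    return RRSeries(patient_id=patient_id, intervals=np.asarray(values, float), label=label)


@pytest.fixture()
def constant_series():
    return make_series([0.8] * 600)
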