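import pytest

from incidentqc.cohort import build_cohort
from incidentqc.simulate import flow_replica_preset, generate_cohort, calibration_preset


@pytest.fixture(scope="session")
def flow_records():
    return generate_cohort(flow_replica_preset())


@pytest.fixture(scope="session")
def calibration_records():
    return generate_cohort(calibration_preset(), seed=1)


@pytest.fixture(scope="session")
def calibration_matrix(calibration_records):
    _, matrix = build_cohort(calibration_records)
    return matrix
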