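import numpy as np
import pytest

from tcusim.dynamics import AnthroParams
from tcusim.geometry import default_geometry, scale_geometry
from tcusim.synthetic_data import (SyntheticCohortSpec, generate_cohort,
                                   generate_dkb_trial)

SEED = 7


@pytest.fixture(scope="session")
def base_geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def cohort_spec():
    return SyntheticCohortSpec()


@pytest.fixture(scope="session")
def cohort(cohort_spec):
    return generate_cohort(cohort_spec, SEED)


@pytest.fixture(scope="session")
def subject(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def subject_geometry(base_geometry, subject):
    return scale_geometry(base_geometry, subject.anthro.tibia_length)


@pytest.fixture(scope="session")
def trial(subject, cohort_spec):
    return generate_dkb_trial(subject, cohort_spec, SEED)


@pytest.fixture(scope="session")
def anthro(subject):
    return subject.anthro
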