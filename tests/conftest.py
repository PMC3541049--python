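import pytest

import trflptools as t
from trflptools.assign import SignatureLibrary, build_matrix
from trflptools.pipeline import RunConfig, process_profiles

#: One seeded synthetic study shared across the suite (3 carbon pools x
#: 3 minerals x 5 dilutions, default noise, duplicate digests).
STUDY_SEED = 42


@pytest.fixture(scope="session")
def study():
    return t.simulate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def bin_tables(study):
    return process_profiles(study.profiles, RunConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def library(study):
    return SignatureLibrary.from_records(study.records)


@pytest.fixture(scope="session")
def matrix(study, bin_tables, library):
    return build_matrix(bin_tables, library)


@pytest.fixture(scope="session")
def thermo_table():
    return t.ThermoTable.default()
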