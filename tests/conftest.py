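import pytest

from oncosep import CohortConfig, generate_cohort
from oncosep.sofa import label_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_control=80, n_sepsis=40, seed=7)


@pytest.fixture(scope="session")
def small_events(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def antibiotic_ids(small_config):
    return [d.drug_id for d in small_config.drug_catalog if d.is_antibiotic]


@pytest.fixture(scope="session")
def small_labels(small_events, antibiotic_ids):
    return label_cohort(small_events, antibiotic_ids=antibiotic_ids)
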