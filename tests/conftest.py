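import pytest

import lbr12 as L


@pytest.fixture(scope="session")
def toy_tables():
    return L.make_toy_fixtures()


@pytest.fixture(scope="session")
def toy_cohort(toy_tables):
    lesions, patients = toy_tables
    return L.build_analysis_cohort(lesions, patients)


@pytest.fixture(scope="session")
def sim_bundle():
    """A moderate simulated cohort shared by survival/integration tests."""
    cfg = L.SimulationConfig(n_patients=4000, seed=123)
    lesions, patients, truth = L.simulate_cohort(cfg, return_patterns=True)
    cohort = L.build_analysis_cohort(lesions, patients)
    classifications = L.classify_cohort(cohort)
    return cfg, cohort, classifications, truth
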