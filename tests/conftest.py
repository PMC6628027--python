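import pytest
from hypothesis import settings as hypothesis_settings

from metaclone import synthetic_cohort as sc

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")


@pytest.fixture(scope="session")
def index_patient():
    """Default study conditions, one seed, full noise."""
    return sc.simulate_patient(sc.index_cohort_spec(seed=1))


@pytest.fixture(scope="session")
def noise_free_patient():
    """Noise-free log2 signal with very deep sequencing: exact-recovery regime."""
    return sc.simulate_patient(sc.index_cohort_spec(seed=3, log2_sigma=0.0,
                                                    depth=10_000))


@pytest.fixture(scope="session")
def index_genotypes():
    return sc.CloneGenotypes(sc.make_index_clone_tree())


@pytest.fixture(scope="session")
def index_analysis(index_patient):
    from metaclone import pipeline as pl
    return pl.analyze_patient(index_patient)


@pytest.fixture(scope="session")
def noise_free_analysis(noise_free_patient):
    from metaclone import pipeline as pl
    return pl.analyze_patient(noise_free_patient)


DIPLOID_SIDE = frozenset({"Pr1", "Pr2", "Pr3"})
WGD_SIDE = frozenset({"Pr4", "VT", "M1", "M2", "M3", "M4"})
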