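import pytest

from mybfam import datasets


@pytest.fixture(scope="session")
def profiles():
    """Default calibrated R2/R3 repeat profiles (shared; calibration scans
    1000 background decoys per profile)."""
    return datasets.load_profiles()


@pytest.fixture(scope="session")
def profile_r2(profiles):
    return profiles[0]


@pytest.fixture(scope="session")
def profile_r3(profiles):
    return profiles[1]


@pytest.fixture(scope="session")
def catalogue():
    return datasets.load_catalogue()


@pytest.fixture(scope="session")
def catalogue_genes(catalogue):
    return datasets.catalogue_gene_models(catalogue)
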