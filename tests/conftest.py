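import numpy as np
import pytest

import nmrmetab as nm


@pytest.fixture(scope="session")
def library():
    return nm.load_library()


@pytest.fixture(scope="session")
def pathway_map():
    return nm.load_pathway_map()


@pytest.fixture(scope="session")
def default_cohort(library):
    """One seeded default cohort: spectra, ground truth, manifest."""
    design = nm.default_design(seed=1)
    spectra, truth, manifest = nm.generate_cohort(design, library=library)
    return spectra, truth, manifest


@pytest.fixture(scope="session")
def normalized_matrix(default_cohort):
    spectra, _, manifest = default_cohort
    return nm.preprocess_spectra(spectra, manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
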