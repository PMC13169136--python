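import warnings

import pytest
from hypothesis import settings

from phenokey.registry import load_registries
from phenokey.rules import AnnotationConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registries():
    return load_registries()


@pytest.fixture(scope="session")
def config():
    return AnnotationConfig()


@pytest.fixture(scope="session")
def table1():
    from phenokey.datasets import load_table1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_table1()


@pytest.fixture(scope="session")
def table1_spectra():
    from phenokey.datasets import load_table1_spectra

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_table1_spectra()


@pytest.fixture(scope="session")
def table1_results(table1_spectra, registries, config):
    """Annotation results for the 39 reference spectra, keyed by id."""
    from phenokey.rules import annotate

    return {
        s.identifier: annotate(s, config, registries) for s in table1_spectra
    }
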