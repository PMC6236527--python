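import pytest

from gwtrace.datamodel import GuidelineRegistry
from gwtrace.fixture import load_study_fixture


@pytest.fixture(scope="session")
def study():
    return load_study_fixture()


@pytest.fixture(scope="session")
def summaries(study):
    return list(study.summaries)


@pytest.fixture(scope="session")
def registry():
    return GuidelineRegistry.who_default()
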