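import pytest
from hypothesis import settings

from oraitraffic import sequences

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def horai1():
    return sequences.load_horai1()


@pytest.fixture(scope="session")
def panel(horai1):
    return dict(sequences.construct_panel(horai1))


@pytest.fixture(scope="session")
def isoform_cterms():
    return {s.id: s for s in sequences.load_isoform_cterms()}
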