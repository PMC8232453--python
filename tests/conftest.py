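import pytest

from netclosure import DirectedGraph, motif_fixtures


@pytest.fixture(scope="session")
def motifs() -> dict[str, DirectedGraph]:
    return motif_fixtures()


@pytest.fixture
def ff3(motifs):
    return motifs["FF3"]


@pytest.fixture
def cy3(motifs):
    return motifs["CY3"]


@pytest.fixture
def bi3(motifs):
    return motifs["BI3"]
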