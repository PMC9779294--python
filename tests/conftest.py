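import pytest

from mecp2locus import build_panel, load_segment_catalog, mecp2_gene_model


@pytest.fixture(scope="session")
def panel():
    return build_panel()


@pytest.fixture(scope="session")
def mecp2():
    return mecp2_gene_model()


@pytest.fixture(scope="session")
def catalog():
    return load_segment_catalog()
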