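import pytest

from mitoinit.riboseq import MitoGeneModel, OverlapRegion


@pytest.fixture
def toy_genes():
    """Two plus-strand genes whose ORFs overlap by 20 nt, plus a
    minus-strand gene, mimicking a bicistronic arrangement."""
    return [
        MitoGeneModel("A", start=100, stop_first=300, strand="+"),
        MitoGeneModel("B", start=280, stop_first=600, strand="+"),
        MitoGeneModel("C", start=1000, stop_first=802, strand="-"),
    ]


@pytest.fixture
def toy_overlaps():
    # ORF A = [100, 303), ORF B = [280, 603): shared interval [280, 303)
    return [OverlapRegion(("A", "B"), 280, 303)]
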