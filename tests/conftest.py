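import pytest

from hdgkit.gene_catalog import GeneCatalog, GeneEntry, load_default_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Small hand-built catalog used by parser and rule tests."""
    entries = [
        GeneEntry("almA", "K00496", "alkane", None, "standalone", False, 480),
        GeneEntry("rubB", "K05297", "alkane", None, "standalone", True, 380),
        GeneEntry("xylA", "K15757", "MAH", "xylAM", "structural", False, 491),
        GeneEntry("xylM", "K15758", "MAH", "xylAM", "structural", False, 365),
        GeneEntry("todC1", "K18074", "MAH", "tod", "structural", False, 450),
        GeneEntry("todC2", "K18075", "MAH", "tod", "structural", False, 187),
        GeneEntry("todA", "K18072", "MAH", "tod", "electron_transport_or_reductase", False, 410),
        GeneEntry("gst", "K00799", "PAH", None, "standalone", True, 219),
        GeneEntry("chnB", "K03379", "various", None, "standalone", False, 542),
    ]
    return GeneCatalog(entries, general_exclusion_list={"rubB", "gst"})
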