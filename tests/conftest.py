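import pytest

from gcnbench import CountTable, GCNDatabase, TaxonProfile


@pytest.fixture
def small_db():
    return GCNDatabase(entries={"Bacteroides": 4.0, "Escherichia": 7.0}, default_gcn=1.8)


@pytest.fixture
def even_mock():
    return TaxonProfile({"Bacteroides": 0.5, "Escherichia": 0.5}, community_id="mock")


@pytest.fixture
def simple_counts():
    return CountTable({"Bacteroides": 400, "Escherichia": 700}, community_id="sample")
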