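import pytest

from patentsearch.corpus import PatentCorpus, PatentDocument, Terminology
from patentsearch.index import IndexConfig, build_index
from patentsearch.synth import SynthConfig, generate_corpus


@pytest.fixture
def tiny_corpus() -> PatentCorpus:
    """Four handmade patents with a small citation structure."""
    docs = [
        PatentDocument(
            patent_id="EP0000001",
            title="Pyrimidine kinase inhibitor",
            abstract="A selective kinase inhibitor for treating ocular hypertension.",
            claims="A compound comprising a pyrimidine core and a kinase binding moiety.",
            description="Detailed synthesis routes and assay protocols for the compound.",
            ipc_codes=["C07D 239/47"],
            cited_ids=[],
        ),
        PatentDocument(
            patent_id="EP0000002",
            title="Kinase assay device",
            abstract="Device for measuring kinase activity in breast cancer samples.",
            claims="An assay device with a fluorescent reporter.",
            description="The device uses microfluidics.",
            ipc_codes=["G01N 33/50"],
            cited_ids=["EP0000001"],
        ),
        PatentDocument(
            patent_id="EP0000003",
            title="Antibody formulation",
            abstract="Stable antibody formulation for cancer therapy.",
            claims="A formulation comprising an antibody and a stabilizer.",
            description="Freeze drying protocols.",
            ipc_codes=["A61K 39/395"],
            cited_ids=["EP0000001", "EP0000002", "US9999999"],
        ),
        PatentDocument(
            patent_id="EP0000004",
            title="Gene therapy vector",
            abstract="Viral vector for gene therapy of retinal disease.",
            claims="A vector comprising a promoter and a therapeutic gene.",
            description="Vector production in cell culture.",
            ipc_codes=["C12N 15/86"],
            cited_ids=["EP0000001"],
        ),
    ]
    return PatentCorpus(iter(docs))


@pytest.fixture
def mesh_terminology() -> Terminology:
    t = Terminology(name="MESH")
    t.add_term("cancer", "MESH", "D009369")
    t.add_term("breast cancer", "MESH", "D001943")
    t.add_term("kinase inhibitor", "MESH", "D047428")
    t.add_term("gene therapy", "MESH", "D015316")
    return t


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    return SynthConfig(n_patents=80, seed=7)


@pytest.fixture(scope="session")
def synth_corpus(synth_config):
    return generate_corpus(synth_config)


@pytest.fixture(scope="session")
def synth_index(synth_corpus):
    return build_index(synth_corpus, IndexConfig())
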