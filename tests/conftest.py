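import pytest

from gsk3pipe import data as paper_data
from gsk3pipe.descriptors import MoleculeGraph


@pytest.fixture(scope="session")
def cytotox():
    return paper_data.load_cytotoxicity()


@pytest.fixture(scope="session")
def dock():
    return paper_data.load_docking()


@pytest.fixture(scope="session")
def compounds():
    return paper_data.load_compounds()


@pytest.fixture(scope="session")
def descriptor_table():
    return {r.compound_id: r for r in paper_data.load_descriptors()}


@pytest.fixture(scope="session")
def graphs():
    return {cid: MoleculeGraph.from_dict(doc)
            for cid, doc in paper_data.load_molecule_graphs().items()}
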