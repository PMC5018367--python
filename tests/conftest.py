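import pytest

import chemannot as ca
from chemannot import demo


@pytest.fixture(scope="session")
def fixture_space():
    """A mid-size seeded synthetic reference space shared across tests."""
    return ca.generate_fixture_space(
        n_chemicals=100, synonyms_per_chemical=3, salt_fraction=0.2, seed=7
    )


@pytest.fixture(scope="session")
def demo_space():
    return demo.nsaid_space()


@pytest.fixture(scope="session")
def demo_bundle():
    return demo.nsaid_bundle()


@pytest.fixture()
def tiny_space():
    """Three chemicals, one shared (ambiguous) synonym."""
    space = ca.ReferenceSpace()
    space.add_record(
        ca.ChemicalRecord(
            chemical_id="CID000000001",
            synonyms={("aspirin", "src"), ("acetylsalicylic acid", "src")},
            inchikeys={"BSYNRYMUTXBXSQ-UHFFFAOYSA-N"},
            smiles={"CC(=O)Oc1ccccc1C(=O)O"},
        )
    )
    space.add_record(
        ca.ChemicalRecord(
            chemical_id="CID000000002",
            synonyms={("mercaptopurine", "src"), ("purinethol", "src")},
        )
    )
    space.add_record(
        ca.ChemicalRecord(
            chemical_id="CID000000003",
            synonyms={("mercaptopurine", "other"), ("salicylic acid", "other")},
        )
    )
    return space
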