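import pytest

import nrpretro as nr
from nrpretro import monomers as M


@pytest.fixture(scope="session")
def packaged_db():
    return nr.packaged_database()


@pytest.fixture(scope="session")
def gly_db():
    return M.database_from_records([{"code": "Gly", "smiles": "NCC(=O)O"}])


@pytest.fixture(scope="session")
def aa20_records():
    """The 20 proteinogenic amino acids, as (code, smiles) records."""
    db = nr.packaged_database()
    codes = [
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    ]
    return [{"code": c, "smiles": db.get(c).smiles} for c in codes]


@pytest.fixture(scope="session")
def aa20_db(aa20_records):
    return M.database_from_records(aa20_records)
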