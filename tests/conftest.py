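from pathlib import Path

import pytest

from csnkit import (
    compute_fingerprints,
    generate_families,
    similarity_matrix,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "data"

ALPHA_PINENE_IFP = DATA_DIR / "ifp_alpha_pinene_dbp.tsv"
GAMMA_MAALIENE_IFP = DATA_DIR / "ifp_gamma_maaliene_kif11.tsv"


@pytest.fixture(scope="session")
def three_family_records():
    """Default labelled three-family fixture (seed 0)."""
    return generate_families(seed=0)


@pytest.fixture(scope="session")
def three_family_fps(three_family_records):
    return compute_fingerprints(three_family_records)


@pytest.fixture(scope="session")
def three_family_matrix(three_family_fps):
    return similarity_matrix(three_family_fps)


@pytest.fixture
def molecule_csv(tmp_path):
    """Small valid molecule table on disk."""
    path = tmp_path / "mols.csv"
    path.write_text(
        "mol_id,name,smiles\n"
        "1,ethanol,CCO\n"
        "2,benzene,c1ccccc1\n"
        "3,limonene,CC(=C)C1CCC(C)=CC1\n",
        encoding="utf-8",
    )
    return path
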