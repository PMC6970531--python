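import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


CHAIN_MAP = {"beta": "C", "beta_prime": "D", "sigma70": "F"}


@pytest.fixture
def chain_map():
    return dict(CHAIN_MAP)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# Minimal hand-written PDB: three ALA residues (N, CA, C for the middle one),
# one Mg hetero site, and an alt-loc pair on residue 2's CB with unequal
# occupancies (B has the higher one).
TINY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  N   ALA A   2       1.000   1.000   0.000  1.00 10.00           N
ATOM      3  CA  ALA A   2       2.000   1.500   0.500  1.00 10.00           C
ATOM      4  C   ALA A   2       3.000   1.200   1.000  1.00 10.00           C
ATOM      5  CB AALA A   2       2.500   2.500   0.700  0.30 10.00           C
ATOM      6  CB BALA A   2       2.600   2.600   0.800  0.70 10.00           C
ATOM      7  CA  ALA A   3       4.000   2.000   1.500  1.00 10.00           C
HETATM    8 MG    MG B 501       5.000   5.000   5.000  1.00 20.00          MG
END
"""


@pytest.fixture
def tiny_pdb_path(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p
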