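import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


MINIMAL_PDB = """\
ATOM      1  N   SER A   2       1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   2       2.000   0.500   0.000  1.00  0.00           C
ATOM      3  CB  SER A   2       2.500   1.500   1.000  1.00  0.00           C
ATOM      4  N   TRP A   3       4.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA  TRP A   3       5.000   0.500   0.000  1.00  0.00           C
ATOM      6  N   GLN A   4       7.000   0.000   0.000  1.00  0.00           N
ATOM      7  CA  GLN A   4       8.000   0.500   0.000  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
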