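import numpy as np
import pytest

from foldscreen import (
    ConfidenceSpec,
    InterfaceSpec,
    make_confidence,
    make_interface_pair,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 85.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 85.00           C
ATOM      3  C   ALA A   1      12.345   7.364  -4.803  1.00 85.00           C
ATOM      4  O   ALA A   1      12.462   8.234  -5.659  1.00 85.00           O
ATOM      5  CB  ALA A   1      12.583   4.887  -5.041  1.00 85.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def planted_pair():
    """A 40+40 residue two-chain model with 12 planted contacts and a
    confident interface."""
    fix = make_interface_pair(
        InterfaceSpec(n_res_a=40, n_res_b=40, n_true_contacts=12, seed=11)
    )
    conf = make_confidence(fix.model, fix.planted, ConfidenceSpec(seed=11))
    return fix, conf


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
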