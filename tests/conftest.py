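import logging

import numpy as np
import pytest

from portalphylo.structures import CaChain, Residue
from portalphylo.synthetic import SyntheticFamilySpec, ca_family

# synthetic chains routinely trip the Cα–Cα geometry warning at flank joints
logging.getLogger("portalphylo.structures").setLevel(logging.ERROR)

TINY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


def chain_from_coords(coords, label="x", aa=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    aa = aa or "A" * n
    return CaChain(
        [Residue(label, i + 1, aa[i], tuple(coords[i])) for i in range(n)],
        source_id=label,
    )


@pytest.fixture(scope="session")
def family_pair():
    """Two-chain family: 60-residue core (σ = 0.3 Å) with 20+20 flanks."""
    spec = SyntheticFamilySpec(
        labels=("A", "B"),
        core_length=60,
        flank_lengths={"A": (20, 20), "B": (20, 20)},
        core_noise={"A": 0.3, "B": 0.3},
        seed=0,
    )
    return ca_family(spec)


@pytest.fixture(scope="session")
def family_four():
    """Four-taxon synthetic family with graded core noise."""
    spec = SyntheticFamilySpec(
        labels=("A", "B", "C", "D"),
        core_length=60,
        core_noise={"A": 0.1, "B": 0.2, "C": 0.35, "D": 0.5},
        seed=11,
    )
    return ca_family(spec)
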