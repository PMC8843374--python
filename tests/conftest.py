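"""Shared fixtures: synthetic families and micro-structures.

Everything is generated programmatically; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from kac3d.model import Atom, Chain, Residue
from kac3d.synthdata import (
    DEMO_DOMAINS,
    DEMO_PLAN,
    DEMO_SITES,
    FamilySpec,
    HomologSpec,
    demo_family_spec,
    generate_family,
)

SEED = 20260923


@pytest.fixture(scope="session")
def demo_family():
    """The standard six-homolog study-condition family."""
    return generate_family(demo_family_spec(SEED))


@pytest.fixture(scope="session")
def clean_family():
    """Noise-free family, all sites conserved, no hinge, no disorder."""
    spec = FamilySpec(
        seed=SEED + 1,
        sse_plan=DEMO_PLAN,
        domains=DEMO_DOMAINS,
        sites=DEMO_SITES,
        homologs=[HomologSpec(identity=idn) for idn in (95.0, 85.0, 75.0, 65.0)],
    )
    return generate_family(spec)


@pytest.fixture(scope="session")
def hinge_family():
    """Every homolog carries a 30° hinge of the C-terminal domain."""
    spec = FamilySpec(
        seed=SEED + 2,
        sse_plan=DEMO_PLAN,
        domains=DEMO_DOMAINS,
        sites=DEMO_SITES,
        homologs=[
            HomologSpec(identity=idn, hinges=[(1, 30.0)]) for idn in (92.0, 80.0, 68.0)
        ],
    )
    return generate_family(spec)


def make_residue(
    number: int,
    name: str = "ALA",
    atoms: dict[str, np.ndarray] | None = None,
    chain: Chain | None = None,
) -> Residue:
    res = Residue(author_number=number, name=name)
    for atom_name, coords in (atoms or {}).items():
        element = atom_name[0] if atom_name[0] in "CNOSH" else atom_name
        res.add_atom(Atom(atom_name, element, np.asarray(coords, dtype=float)))
    if chain is not None:
        chain.add_residue(res)
    return res


THREE_RESIDUE_PDB = """\
ATOM      1  N   MET A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  MET A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   MET A   1      12.759   7.092  -4.973  1.00  0.00           C
ATOM      4  O   MET A   1      13.164   7.768  -5.923  1.00  0.00           O
ATOM      5  N   LYS A   2      13.256   7.215  -3.744  1.00  0.00           N
ATOM      6  CA  LYS A   2      14.321   8.163  -3.438  1.00  0.00           C
ATOM      7  C   LYS A   2      15.583   7.853  -4.239  1.00  0.00           C
ATOM      8  O   LYS A   2      15.612   6.868  -4.974  1.00  0.00           O
ATOM      9  N   ALA A   3      16.602   8.691  -4.113  1.00  0.00           N
ATOM     10  CA  ALA A   3      17.874   8.505  -4.805  1.00  0.00           C
ATOM     11  C   ALA A   3      18.577   7.230  -4.350  1.00  0.00           C
ATOM     12  O   ALA A   3      18.053   6.496  -3.510  1.00  0.00           O
TER
END
"""


@pytest.fixture()
def three_residue_pdb() -> str:
    return THREE_RESIDUE_PDB
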