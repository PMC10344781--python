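"""Shared fixtures: a planted toy antibody--pMHC complex and tiny PDB files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tcrmkit.toy_complex import PlantedContact as PC
from tcrmkit.toy_complex import ToyComplexSpec, make_toy_complex

# Planted interface used across the structural tests:
#   light-chain 32 touches peptide positions P4, P5, P7, P8 (4 contacts, class P)
#   light-chain 27 -> P2 (P);  heavy-chain 100 -> P5 (P)
#   heavy-chain 98 -> P6 and MHC 65 (PM)
#   heavy-chain 53 -> MHC 65 (M);  light-chain 50 -> MHC 146, 151 (M)
TOY_CONTACTS = (
    [PC("L", 32, ("P", p)) for p in (4, 5, 7, 8)]
    + [PC("L", 27, ("P", 2)), PC("H", 100, ("P", 5)), PC("H", 98, ("P", 6))]
    + [PC("H", 98, ("M", 65)), PC("L", 50, ("M", 146)),
       PC("L", 50, ("M", 151)), PC("H", 53, ("M", 65))]
)

TOY_SPEC = ToyComplexSpec(
    peptide_sequence="SIINFEKL",
    contacts=TOY_CONTACTS,
    mhc_residue_names={65: "ARG", 146: "LYS", 151: "HIS"},
    ab_residue_names={("L", 32): "GLN"},
)


@pytest.fixture(scope="session")
def toy():
    """(AnnotatedComplex, planted-truth table) for the standard toy complex."""
    return make_toy_complex(TOY_SPEC)


@pytest.fixture(scope="session")
def toy_cx(toy):
    return toy[0]


@pytest.fixture()
def tiny_pdb(tmp_path):
    """A hand-written 5-atom single-chain PDB file."""
    text = (
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
        "ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O\n"
        "ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "tiny.pdb"
    p.write_text(text)
    return p


@pytest.fixture()
def altloc_pdb(tmp_path):
    """One atom with two alternate locations, A at higher occupancy."""
    text = (
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C\n"
        "ATOM      3  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "altloc.pdb"
    p.write_text(text)
    return p


def make_sequence_toy(lengths: dict[str, int], motifs: dict[str, str] | None = None
                      ) -> pd.DataFrame:
    """Atom table of CA-only chains with given lengths (for role heuristics)."""
    from tcrmkit.structure import ATOM_COLUMNS

    motifs = motifs or {}
    rows = []
    offset = 0.0
    for chain, n in lengths.items():
        motif = motifs.get(chain, "")
        for i in range(1, n + 1):
            resname = "ALA"
            if motif and i > n - len(motif):
                one = motif[i - (n - len(motif)) - 1]
                from tcrmkit.toy_complex import ONE_TO_THREE
                resname = ONE_TO_THREE[one]
            rows.append((chain, i, "", resname, "CA", "C",
                         offset + 3.8 * i, 0.0, 0.0, 1.0, "", True, False))
        offset += 1000.0
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)


def random_atom_cloud(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(-8, 8, size=(n, 3))
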