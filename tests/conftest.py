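"""Shared fixtures: tiny in-memory chains and PDB snippets."""

from __future__ import annotations

import numpy as np
import pytest

from exonppi.structio import AtomRecord, ChainStructure


def make_random_chain(
    rng: np.random.Generator,
    chain_id: str,
    n_residues: int,
    box: float = 25.0,
    hydrogen_rate: float = 0.2,
) -> ChainStructure:
    """Random chain: 1-3 heavy atoms per residue plus occasional hydrogens."""
    atoms = []
    for i in range(n_residues):
        for _ in range(int(rng.integers(1, 4))):
            el = str(rng.choice(["C", "N", "O", "S"]))
            atoms.append(
                AtomRecord(
                    name=el + "X",
                    element=el,
                    coords=tuple(rng.uniform(0, box, 3)),
                    residue_index=i,
                    author_number=i + 1,
                    is_heavy=True,
                )
            )
        if rng.random() < hydrogen_rate:
            atoms.append(
                AtomRecord(
                    name="H",
                    element="H",
                    coords=tuple(rng.uniform(0, box, 3)),
                    residue_index=i,
                    author_number=i + 1,
                    is_heavy=False,
                )
            )
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_residues))
    return ChainStructure(
        chain_id=chain_id,
        sequence=seq,
        atoms=atoms,
        author_numbers=list(range(1, n_residues + 1)),
    )


def point_chain(
    chain_id: str, positions: list[tuple[float, float, float]], element: str = "C"
) -> ChainStructure:
    """One heavy atom per residue at the given positions."""
    atoms = [
        AtomRecord(
            name="CA",
            element=element,
            coords=tuple(map(float, p)),
            residue_index=i,
            author_number=i + 1,
            is_heavy=element in "CNOS",
        )
        for i, p in enumerate(positions)
    ]
    return ChainStructure(
        chain_id=chain_id,
        sequence="A" * len(positions),
        atoms=atoms,
        author_numbers=list(range(1, len(positions) + 1)),
    )


TWO_RESIDUE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER       4      GLY A   2
ATOM      5  CA  SER B   1       0.000   5.000   0.000  1.00  0.00           C
ATOM      6  CA  THR B   2       3.800   5.000   0.000  1.00  0.00           C
TER       7      THR B   2
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.70  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.30  0.00           C
ATOM      3  CA  GLY B   1       0.000   2.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "two_residue.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path
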