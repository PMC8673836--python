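import numpy as np
import pytest

from resnominate.structure_io import Atom, Chain, ComplexStructure, Residue

DNA_ATOM_NAMES = ["P", "OP1", "OP2", "O5'", "C1'", "C4'", "O4'", "N1", "N3", "C2", "N7"]
PROTEIN_ATOM_NAMES = ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ"]


def random_complex(rng: np.random.Generator, n_protein_res=3, n_dna_res=2,
                   atoms_per_res=4, box=12.0, structure_id="random"):
    """A geometrically random protein-DNA complex for oracle comparisons."""

    def atoms(names):
        return [
            Atom(name, name[0], rng.uniform(0, box, size=3))
            for name in rng.choice(names, size=atoms_per_res, replace=False)
        ]

    protein = [
        Residue("A", 100 + i, "GLY", atoms(PROTEIN_ATOM_NAMES)) for i in range(n_protein_res)
    ]
    dna = [Residue("D", i + 1, "DA", atoms(DNA_ATOM_NAMES)) for i in range(n_dna_res)]
    return ComplexStructure(
        id=structure_id,
        chains=[Chain("A", "protein", protein), Chain("D", "dna", dna)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_complex():
    """One GLY residue and one DA nucleotide; single contact at 3.9 A."""
    protein = [
        Residue(
            "A",
            1,
            "GLY",
            [
                Atom("N", "N", [0.0, 0.0, 0.0]),
                Atom("CA", "C", [1.5, 0.0, 0.0]),
                Atom("C", "C", [2.2, 1.2, 0.0]),
            ],
        )
    ]
    dna = [
        Residue(
            "D",
            1,
            "DA",
            [
                Atom("P", "P", [1.5, 3.9, 0.0]),
                Atom("OP1", "O", [1.5, 5.4, 0.0]),
                Atom("N1", "N", [8.0, 8.0, 8.0]),
            ],
        )
    ]
    return ComplexStructure(
        id="tiny", chains=[Chain("A", "protein", protein), Chain("D", "dna", dna)]
    )
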