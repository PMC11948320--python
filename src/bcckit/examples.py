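"""Hand-built example molecules used in docs, demos and tests."""

from __future__ import annotations

import numpy as np

from .chem import Atom, Bond, Molecule
from .conformers import build_chain_conformer

__all__ = ["methane", "ethanol", "ethylene_glycol", "benzene", "acetate",
           "nitromethane", "GLYCOL_BACKBONE"]


def methane() -> Molecule:
    atoms = [Atom(0, "C")] + [Atom(i, "H") for i in range(1, 5)]
    bonds = [Bond(0, i) for i in range(1, 5)]
    t = 1.09 / np.sqrt(3.0)
    coords = np.array([[0, 0, 0], [t, t, t], [t, -t, -t],
                       [-t, t, -t], [-t, -t, t]], float)
    return Molecule("methane", atoms, bonds, [coords])


def ethanol() -> Molecule:
    """CH3-CH2-OH; atoms: C0 C1 O2 H3..H8 (H8 hydroxyl)."""
    atoms = [Atom(0, "C"), Atom(1, "C"), Atom(2, "O")]
    atoms += [Atom(i, "H") for i in range(3, 9)]
    bonds = [Bond(0, 1), Bond(1, 2),
             Bond(0, 3), Bond(0, 4), Bond(0, 5),
             Bond(1, 6), Bond(1, 7), Bond(2, 8)]
    return Molecule("ethanol", atoms, bonds)


#: backbone H-O-C-C-O-H of ethylene glycol, as atom indices
GLYCOL_BACKBONE = [6, 2, 0, 1, 3, 7]


def ethylene_glycol(states: tuple[str, ...] = ("t", "t", "t")) -> Molecule:
    """HO-CH2-CH2-OH with a conformer realizing the given rotamer states.

    Atoms: C0, C1, O2 (on C0), O3 (on C1), H4/H5 (on C0), H8/H9 (on C1),
    H6 (on O2), H7 (on O3).  The three consecutive backbone dihedrals are
    H6-O2-C0-C1, O2-C0-C1-O3 and C0-C1-O3-H7.
    """
    atoms = [Atom(0, "C"), Atom(1, "C"), Atom(2, "O"), Atom(3, "O"),
             Atom(4, "H"), Atom(5, "H"), Atom(6, "H"), Atom(7, "H"),
             Atom(8, "H"), Atom(9, "H")]
    bonds = [Bond(0, 1), Bond(0, 2), Bond(1, 3),
             Bond(0, 4), Bond(0, 5), Bond(1, 8), Bond(1, 9),
             Bond(2, 6), Bond(3, 7)]
    mol = Molecule("ethylene_glycol", atoms, bonds)
    coords = build_chain_conformer(mol, GLYCOL_BACKBONE, states)
    mol.add_conformer(coords)
    return mol


def benzene() -> Molecule:
    atoms = [Atom(i, "C") for i in range(6)]
    atoms += [Atom(i, "H") for i in range(6, 12)]
    bonds = [Bond(i, (i + 1) % 6, "aromatic") for i in range(6)]
    bonds += [Bond(i, i + 6) for i in range(6)]
    coords = np.zeros((12, 3))
    for i in range(6):
        ang = np.pi * i / 3.0
        coords[i] = [1.397 * np.cos(ang), 1.397 * np.sin(ang), 0.0]
        coords[i + 6] = [2.48 * np.cos(ang), 2.48 * np.sin(ang), 0.0]
    return Molecule("benzene", atoms, bonds, [coords])


def acetate() -> Molecule:
    """CH3-COO(-): carboxylate carbon C1, oxygens O2 (=O) and O3 (-O)."""
    atoms = [Atom(0, "C"), Atom(1, "C"), Atom(2, "O"), Atom(3, "O", -1),
             Atom(4, "H"), Atom(5, "H"), Atom(6, "H")]
    bonds = [Bond(0, 1), Bond(1, 2, "double"), Bond(1, 3),
             Bond(0, 4), Bond(0, 5), Bond(0, 6)]
    return Molecule("acetate", atoms, bonds)


def nitromethane() -> Molecule:
    """CH3-NO2 with formal charges N(+1), one O(-1)."""
    atoms = [Atom(0, "C"), Atom(1, "N", +1), Atom(2, "O"), Atom(3, "O", -1),
             Atom(4, "H"), Atom(5, "H"), Atom(6, "H")]
    bonds = [Bond(0, 1), Bond(1, 2, "double"), Bond(1, 3),
             Bond(0, 4), Bond(0, 5), Bond(0, 6)]
    return Molecule("nitromethane", atoms, bonds)
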