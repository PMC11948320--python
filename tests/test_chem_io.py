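"""Molecular graph model, mol2/xyz parsing, rings and equivalence."""

import itertools

import networkx as nx
import numpy as np
import pytest

from bcckit.chem import (
    Atom,
    Bond,
    Molecule,
    MoleculeError,
    automorphism_orbits,
    equivalence_classes,
    ring_info,
)
from bcckit.io import (
    ParseError,
    read_mol2,
    read_xyz,
    round_preserving_sum,
    write_mol2,
)

from conftest import MOL2_METHANE, XYZ_WATER, random_molecules


class TestMoleculeModel:
    def test_net_charge_is_sum_of_formal_charges(self):
        mol = Molecule("x", [Atom(0, "O", -1), Atom(1, "H")], [Bond(0, 1)])
        assert mol.net_charge == -1

    def test_dangling_bond_rejected(self):
        with pytest.raises(MoleculeError, match="missing atom"):
            Molecule("x", [Atom(0, "C"), Atom(1, "H")],
                     [Bond(0, 1), Bond(0, 5)])

    def test_duplicate_bond_rejected(self):
        with pytest.raises(MoleculeError, match="duplicate"):
            Molecule("x", [Atom(0, "C"), Atom(1, "O")],
                     [Bond(0, 1), Bond(1, 0)])

    def test_disconnected_graph_rejected(self):
        with pytest.raises(MoleculeError, match="not connected"):
            Molecule("x", [Atom(0, "O"), Atom(1, "O"),
                           Atom(2, "H"), Atom(3, "H")],
                     [Bond(0, 2), Bond(1, 3)])

    def test_conformer_shape_checked(self):
        with pytest.raises(MoleculeError, match="conformer shape"):
            Molecule("x", [Atom(0, "C"), Atom(1, "H")], [Bond(0, 1)],
                     [np.zeros((3, 3))])


class TestMol2:
    def test_methane_fixture(self):
        mol = read_mol2(MOL2_METHANE)
        assert mol.n_atoms == 5
        assert [a.element for a in mol.atoms] == ["C", "H", "H", "H", "H"]
        assert all(b.order == "single" for b in mol.bonds)
        assert len(mol.bonds) == 4
        assert mol.net_charge == 0
        assert mol.precharges is None  # all-zero column is not a charge set

    def test_bond_to_nonexistent_atom(self):
        bad = MOL2_METHANE.replace("4 1 5 1", "4 1 99 1")
        with pytest.raises(ParseError, match="99"):
            read_mol2(bad)

    def test_unknown_bond_order_token(self):
        bad = MOL2_METHANE.replace("4 1 5 1", "4 1 5 zz")
        with pytest.raises(ParseError, match="zz"):
            read_mol2(bad)

    def test_missing_section(self):
        with pytest.raises(ParseError, match="MOLECULE"):
            read_mol2("@<TRIPOS>ATOM\n1 C1 0 0 0 C.3 1 MOL 0.0\n")

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip_random_molecules(self, seed):
        mol = random_molecules(1, start_seed=100 + seed)[0]
        text = write_mol2(mol)
        back = read_mol2(text)
        assert back.n_atoms == mol.n_atoms
        assert {b.key for b in back.bonds} == {b.key for b in mol.bonds}
        assert [a.element for a in back.atoms] == mol.elements()
        assert np.allclose(back.conformers[0], mol.conformers[0], atol=1e-4)
        # second serialization is byte-stable
        assert write_mol2(back) == text

    def test_formal_charges_survive_round_trip(self):
        mol = Molecule("ox", [Atom(0, "O", -1), Atom(1, "H")], [Bond(0, 1)],
                       [np.array([[0.0, 0, 0], [0.96, 0, 0]])])
        back = read_mol2(write_mol2(mol))
        assert [a.formal_charge for a in back.atoms] == [-1, 0]
        assert back.net_charge == -1

    def test_aromatic_and_amide_tokens_round_trip(self, benzene):
        back = read_mol2(write_mol2(benzene))
        assert sum(b.order == "aromatic" for b in back.bonds) == 6
        amide = MOL2_METHANE.replace("1 1 2 1", "1 1 2 am")
        assert read_mol2(amide).bonds[0].order == "amide"

    def test_split_multi_fragment(self):
        text = (
            "@<TRIPOS>MOLECULE\nm\n4 2 1 0 0\nSMALL\nNO_CHARGES\n"
            "@<TRIPOS>ATOM\n"
            "1 O1 0 0 0 O.3 1 A 0.0\n2 H1 0.96 0 0 H 1 A 0.0\n"
            "3 O2 5 5 5 O.3 1 A 0.0\n4 H2 5.96 5 5 H 1 A 0.0\n"
            "@<TRIPOS>BOND\n1 1 2 1\n2 3 4 1\n"
        )
        with pytest.raises(ParseError, match="not connected"):
            read_mol2(text)
        frags = read_mol2(text, split=True)
        assert len(frags) == 2
        assert all(f.n_atoms == 2 for f in frags)

    def test_written_charges_sum_to_net_charge_exactly(self, methane):
        text = write_mol2(methane, np.array([-0.4, 0.1, 0.1, 0.1, 0.1]))
        col = [float(ln.split()[-1]) for ln in text.splitlines()
               if ln and ln[0] != "@" and len(ln.split()) == 9]
        assert len(col) == 5
        assert sum(round(c * 1e6) for c in col) == 0

    def test_no_charges_written_as_zero(self, methane):
        text = write_mol2(methane)
        assert " 0.000000" in text

    def test_charge_length_mismatch(self, methane):
        with pytest.raises(ValueError, match="length"):
            write_mol2(methane, np.zeros(3))


class TestLargestRemainderRounding:
    def brute_force(self, values, target, decimals=6):
        """Independent apportionment oracle: integer-unit floor + greedy
        hand-out by remainder."""
        scale = 10 ** decimals
        units = [int(np.floor(v * scale)) for v in values]
        rem = [v * scale - u for v, u in zip(values, units)]
        deficit = round(target * scale) - sum(units)
        order = sorted(range(len(values)), key=lambda i: (-rem[i], i))
        for k in range(abs(deficit)):
            units[order[k]] += 1 if deficit > 0 else 0
        return [u / scale for u in units]

    def test_thirds_sum_to_one(self):
        out = round_preserving_sum(np.array([1 / 3, 1 / 3, 1 / 3]), 1.0)
        assert round(out.sum() * 1e6) == 1_000_000
        assert out.tolist() == self.brute_force([1 / 3] * 3, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_vectors_match_oracle_sum(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=7)
        target = float(np.round(v.sum()))
        v = v + (target - v.sum()) / 7  # make the exact sum an integer
        out = round_preserving_sum(v, target)
        assert round(out.sum() * 1e6) == round(target * 1e6)
        assert np.all(np.abs(out - v) < 1e-6 + 1e-12)


class TestXyz:
    def test_water_bond_perception(self):
        mol = read_xyz(XYZ_WATER)
        pairs = {b.key for b in mol.bonds}
        assert pairs == {(0, 1), (0, 2)}  # two O-H, no H-H

    def test_perception_off(self):
        mol = read_xyz(XYZ_WATER, perceive_bonds=False)
        assert mol.bonds == []

    def test_count_mismatch(self):
        bad = XYZ_WATER.replace("3\n", "4\n")
        with pytest.raises(ParseError, match="fewer"):
            read_xyz(bad)

    def test_unknown_element(self):
        bad = XYZ_WATER.replace("O ", "Xx")
        with pytest.raises(ParseError, match="unknown element"):
            read_xyz(bad)

    def test_perception_symmetric_under_atom_reordering(self):
        lines = XYZ_WATER.splitlines()
        flipped = "\n".join(lines[:2] + [lines[4], lines[3], lines[2]]) + "\n"
        mol = read_xyz(flipped)
        assert {b.key for b in mol.bonds} == {(0, 2), (1, 2)}


def _cyclohexane():
    atoms = [Atom(i, "C") for i in range(6)]
    bonds = [Bond(i, (i + 1) % 6) for i in range(6)]
    return Molecule("cyclohexane", atoms, bonds)


def _fused_bicyclic():
    """Six-ring with a chord 0-2: atoms 0,1,2 sit on a 3-ring."""
    atoms = [Atom(i, "C") for i in range(6)]
    bonds = [Bond(i, (i + 1) % 6) for i in range(6)] + [Bond(0, 2)]
    return Molecule("fused", atoms, bonds)


class TestRings:
    def test_benzene_all_aromatic_size6(self, benzene):
        ri = ring_info(benzene)
        assert ri.smallest_ring_size[:6] == (6,) * 6
        assert all(ri.aromatic[:6])
        assert not any(ri.aromatic[6:])
        assert ri.smallest_ring_size[6:] == (0,) * 6

    def test_cyclohexane_not_aromatic(self):
        ri = ring_info(_cyclohexane())
        assert ri.smallest_ring_size == (6,) * 6
        assert not any(ri.aromatic)

    def test_fused_bicyclic_matches_cycle_enumeration(self):
        mol = _fused_bicyclic()
        ri = ring_info(mol)
        # oracle: enumerate every simple cycle and take, per atom, the
        # length of the smallest one containing it
        g = mol.graph()
        best = {i: 0 for i in range(mol.n_atoms)}
        for cyc in nx.simple_cycles(g):
            if len(cyc) < 3:
                continue
            for v in cyc:
                if best[v] == 0 or len(cyc) < best[v]:
                    best[v] = len(cyc)
        assert ri.smallest_ring_size == tuple(best[i] for i in range(6))
        assert ri.smallest_ring_size[0] == 3  # bridging atoms: smaller ring
        assert ri.smallest_ring_size[4] == 5


class TestEquivalence:
    def test_methane_two_classes(self, methane):
        part = equivalence_classes(methane)
        assert part.n_classes == 2
        assert len({part.class_ids[i] for i in (1, 2, 3, 4)}) == 1

    def test_ethylene_glycol_four_classes(self, glycol):
        part = equivalence_classes(glycol)
        assert part.n_classes == 4
        groups = {frozenset(m) for m in part.members().values()}
        assert groups == {
            frozenset({0, 1}),        # carbons
            frozenset({2, 3}),        # oxygens
            frozenset({6, 7}),        # hydroxyl H
            frozenset({4, 5, 8, 9}),  # methylene H
        }

    @pytest.mark.parametrize("seed", range(8))
    def test_invariant_under_relabeling(self, seed):
        mol = random_molecules(1, start_seed=300 + seed)[0]
        part = equivalence_classes(mol)
        rng = np.random.default_rng(seed)
        perm = list(rng.permutation(mol.n_atoms))
        permuted = mol.permuted(perm)
        part2 = equivalence_classes(permuted)
        # mapping back must reproduce the same partition structure
        for i in range(mol.n_atoms):
            for j in range(mol.n_atoms):
                same = part.class_ids[i] == part.class_ids[j]
                same2 = part2.class_ids[perm[i]] == part2.class_ids[perm[j]]
                assert same == same2

    @pytest.mark.parametrize("builder", [
        _cyclohexane,
        _fused_bicyclic,
        lambda: Molecule("chain", [Atom(0, "C"), Atom(1, "C"), Atom(2, "O"),
                                   Atom(3, "H"), Atom(4, "H")],
                         [Bond(0, 1), Bond(1, 2), Bond(0, 3), Bond(0, 4)]),
    ])
    def test_never_finer_than_automorphism_orbits(self, builder):
        mol = builder()
        part = equivalence_classes(mol)
        orbits = automorphism_orbits(mol)
        # atoms in one orbit must share a refinement class
        for i in range(mol.n_atoms):
            for j in range(mol.n_atoms):
                if orbits.class_ids[i] == orbits.class_ids[j]:
                    assert part.class_ids[i] == part.class_ids[j]

    @pytest.mark.parametrize("seed", range(10))
    def test_never_finer_than_orbits_random_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        # random connected tree + possible extra edge, all carbons
        edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
        mol = Molecule("g", [Atom(i, "C") for i in range(n)],
                       [Bond(a, b) for a, b in edges])
        part = equivalence_classes(mol)
        orbits = automorphism_orbits(mol)
        for i, j in itertools.combinations(range(n), 2):
            if orbits.class_ids[i] == orbits.class_ids[j]:
                assert part.class_ids[i] == part.class_ids[j]
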