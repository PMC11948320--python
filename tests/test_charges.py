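"""EEM pre-charges, BCC application, incidence matrix, symmetrization."""

import numpy as np
import pytest

from bcckit.atom_typing import assign_atom_types, assign_bond_keys
from bcckit.charges import (
    BCCTable,
    ChargeError,
    ChargeSet,
    EEMParams,
    PreChargeSet,
    apply_bcc,
    incidence_matrix,
    normalize_precharges,
    precharges_eem,
    symmetrize_charges,
)
from bcckit.chem import Atom, Bond, Molecule, equivalence_classes
from bcckit.fixtures import FixtureSpec, synth_bcc_table

from conftest import random_molecules


def _diatomic(el_a, el_b, r):
    return Molecule(
        "di", [Atom(0, el_a), Atom(1, el_b)], [Bond(0, 1)],
        [np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])],
    )


class TestEEM:
    def test_homonuclear_neutral_diatomic_zero_charges(self):
        q = precharges_eem(_diatomic("O", "O", 1.48)).charges
        assert np.allclose(q, 0.0, atol=1e-12)

    @pytest.mark.parametrize("pair,r", [(("C", "O"), 1.43),
                                        (("H", "O"), 0.96),
                                        (("C", "N"), 1.47)])
    def test_heteronuclear_matches_two_site_closed_form(self, pair, r):
        # oracle: eliminate the Lagrange multiplier by hand for two sites
        # with q2 = -q1: q1 = (chi2 - chi1) / (2 eta1 + 2 eta2 - 2 kappa/r)
        params = EEMParams.default()
        a, b = pair
        expected = (params.chi[b] - params.chi[a]) / (
            2 * params.eta[a] + 2 * params.eta[b] - 2 * params.kappa / r
        )
        q = precharges_eem(_diatomic(a, b, r)).charges
        assert q[0] == pytest.approx(expected, abs=1e-12)
        assert q.sum() == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_conformation_gives_class_equal_charges(self, glycol):
        q = precharges_eem(glycol).charges
        part = equivalence_classes(glycol)
        for members in part.members().values():
            assert np.ptp(q[list(members)]) < 1e-10

    def test_charged_species_sums_to_net_charge(self):
        hydroxide = Molecule(
            "oh-", [Atom(0, "O", -1), Atom(1, "H")], [Bond(0, 1)],
            [np.array([[0.0, 0, 0], [0.96, 0, 0]])])
        q = precharges_eem(hydroxide).charges
        assert q.sum() == pytest.approx(-1.0, abs=1e-12)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ChargeError, match="singular"):
            precharges_eem(_diatomic("C", "O", 0.0))

    def test_missing_element_parameter(self):
        params = EEMParams(chi={"C": 6.0}, eta={"C": 14.0})
        with pytest.raises(ChargeError, match="O"):
            precharges_eem(_diatomic("C", "O", 1.4), params=params)


class TestNormalizePrecharges:
    def test_small_residual_spread_uniformly(self):
        out = normalize_precharges(np.array([0.0001, 0.0001, 0.0001]), 0)
        assert out.charges.sum() == pytest.approx(0.0, abs=1e-15)
        assert np.ptp(out.charges) < 1e-15
        assert out.provenance == "zero-spread"

    def test_large_residual_is_an_error(self):
        with pytest.raises(ChargeError, match="net charge"):
            normalize_precharges(np.array([0.01, 0.0]), 0)


class TestApplyBcc:
    def test_zero_table_is_identity(self, methane):
        types = assign_atom_types(methane)
        keys = assign_bond_keys(methane, types)
        pre = PreChargeSet(np.array([-0.4, 0.1, 0.1, 0.1, 0.1]))
        out = apply_bcc(methane, types, keys, pre, BCCTable({}))
        assert np.array_equal(out.charges, pre.charges)

    def test_methane_worked_example(self, methane):
        # per-bond oracle: b(c3->hc) = -0.05 moves -0.05 from each H to C
        types = assign_atom_types(methane)
        keys = assign_bond_keys(methane, types)
        pre = PreChargeSet(np.array([-0.40, 0.10, 0.10, 0.10, 0.10]))
        table = BCCTable({("c3", "hc", "single"): -0.05})
        out = apply_bcc(methane, types, keys, pre, table)
        assert out.charges == pytest.approx([-0.60, 0.15, 0.15, 0.15, 0.15])
        assert out.charges.sum() == pytest.approx(0.0, abs=1e-12)

    def test_missing_key_strict_raises_naming_key(self, methane):
        types = assign_atom_types(methane)
        keys = assign_bond_keys(methane, types)
        pre = PreChargeSet(np.zeros(5))
        with pytest.raises(ChargeError, match="c3"):
            apply_bcc(methane, types, keys, pre, BCCTable({}), strict=True)

    @pytest.mark.parametrize("batch", range(5))
    def test_conservation_on_500_random_fixtures(self, batch):
        # 5 x 100 molecules; exact conservation of the net charge
        for k in range(100):
            seed = 1000 + batch * 100 + k
            mol = random_molecules(1, start_seed=seed)[0]
            spec = FixtureSpec(seed=seed)
            types = assign_atom_types(mol)
            keys = assign_bond_keys(mol, types)
            table = synth_bcc_table(spec, [kk.pair for kk in keys])
            pre = precharges_eem(mol)
            out = apply_bcc(mol, types, keys, pre, table)
            assert abs(out.charges.sum() - mol.net_charge) < 1e-12

    def test_negating_table_negates_corrections(self):
        mol = random_molecules(1, start_seed=7)[0]
        types = assign_atom_types(mol)
        keys = assign_bond_keys(mol, types)
        spec = FixtureSpec(seed=7)
        table = synth_bcc_table(spec, [k.pair for k in keys])
        neg = BCCTable({k: -v for k, v in table.values.items()})
        pre = precharges_eem(mol)
        d_pos = apply_bcc(mol, types, keys, pre, table).charges - pre.charges
        d_neg = apply_bcc(mol, types, keys, pre, neg).charges - pre.charges
        assert np.allclose(d_pos, -d_neg, atol=1e-15)

    def test_permutation_equivariance(self):
        mol = random_molecules(1, start_seed=11)[0]
        spec = FixtureSpec(seed=11)
        types = assign_atom_types(mol)
        keys = assign_bond_keys(mol, types)
        table = synth_bcc_table(spec, [k.pair for k in keys])
        pre = precharges_eem(mol)
        out = apply_bcc(mol, types, keys, pre, table).charges
        perm = list(np.random.default_rng(3).permutation(mol.n_atoms))
        pmol = mol.permuted(perm)
        ptypes = assign_atom_types(pmol)
        pkeys = assign_bond_keys(pmol, ptypes)
        ppre = PreChargeSet(np.asarray([pre.charges[perm.index(k)]
                                        for k in range(mol.n_atoms)]))
        pout = apply_bcc(pmol, ptypes, pkeys, ppre, table).charges
        assert np.allclose([pout[perm[i]] for i in range(mol.n_atoms)], out,
                           atol=1e-12)

    def test_corrections_identical_across_conformers(self, glycol):
        # conformation enters only through the pre-charges
        from bcckit.examples import ethylene_glycol

        other = ethylene_glycol(("g+", "t", "g-"))
        types = assign_atom_types(glycol)
        keys = assign_bond_keys(glycol, types)
        table = BCCTable.default()
        p1 = precharges_eem(glycol)
        p2 = precharges_eem(other)
        d1 = apply_bcc(glycol, types, keys, p1, table).charges - p1.charges
        d2 = apply_bcc(other, types, keys, p2, table).charges - p2.charges
        assert np.allclose(d1, d2, atol=1e-15)
        # and the correction operator itself is conformation-free:
        zero = PreChargeSet(np.zeros(glycol.n_atoms))
        c1 = apply_bcc(glycol, types, keys, zero, table).charges
        c2 = apply_bcc(other, types, keys, zero, table).charges
        assert np.array_equal(c1, c2)


class TestIncidenceMatrix:
    def test_methane_single_column(self, methane):
        types = assign_atom_types(methane)
        keys = assign_bond_keys(methane, types)
        a = incidence_matrix(methane, keys, [("c3", "hc", "single")])
        assert a.shape == (5, 1)
        assert a[0, 0] == 4  # carbon is the canonical (alpha) end, 4 bonds
        assert np.all(a[1:, 0] == -1)

    def test_columns_sum_to_zero_arbitrary_molecules(self):
        for mol in random_molecules(10, start_seed=500):
            types = assign_atom_types(mol)
            keys = assign_bond_keys(mol, types)
            order = sorted({k.pair for k in keys if not k.is_self_pair})
            a = incidence_matrix(mol, keys, order)
            assert np.all(a.sum(axis=0) == 0)

    @pytest.mark.parametrize("batch", range(4))
    def test_equivalence_with_apply_bcc_200_fixtures(self, batch):
        for k in range(50):
            seed = 2000 + batch * 50 + k
            mol = random_molecules(1, start_seed=seed)[0]
            spec = FixtureSpec(seed=seed)
            types = assign_atom_types(mol)
            keys = assign_bond_keys(mol, types)
            order = sorted({kk.pair for kk in keys if not kk.is_self_pair})
            table = synth_bcc_table(spec, order)
            b = np.array([table.values[p] for p in order])
            pre = precharges_eem(mol)
            via_loop = apply_bcc(mol, types, keys, pre, table).charges
            via_matrix = pre.charges + incidence_matrix(mol, keys, order) @ b
            assert np.allclose(via_loop, via_matrix, atol=1e-12)

    def test_self_pair_key_has_no_column(self, methane):
        types = assign_atom_types(methane)
        keys = assign_bond_keys(methane, types)
        with pytest.raises(ChargeError, match="self-pair"):
            incidence_matrix(methane, keys, [("c3", "c3", "single")])


class TestBCCTable:
    def test_self_pair_entry_rejected(self):
        with pytest.raises(ChargeError, match="self-pair"):
            BCCTable.from_text("c3\tc3\tsingle\t0.1\n")

    def test_non_canonical_line_is_flipped_with_sign(self):
        table = BCCTable.from_text("hc\tc3\tsingle\t0.05\n")
        assert table.values[("c3", "hc", "single")] == pytest.approx(-0.05)

    def test_orientation_aware_lookup(self):
        from bcckit.atom_typing import BondTypeKey

        table = BCCTable({("c3", "hc", "single"): 0.02})
        along = BondTypeKey("c3", "hc", "single", +1)
        against = BondTypeKey("c3", "hc", "single", -1)
        assert table.lookup(along) == pytest.approx(0.02)
        assert table.lookup(against) == pytest.approx(-0.02)

    def test_round_trip(self):
        table = BCCTable({("c3", "hc", "single"): 0.02,
                          ("c", "o", "delocalized"): -0.11})
        back = BCCTable.from_text(table.to_text())
        assert back.values == pytest.approx(table.values)


class TestSymmetrize:
    def test_class_mean_assigned(self, methane):
        part = equivalence_classes(methane)
        cs = ChargeSet(np.array([-0.6, 0.14, 0.15, 0.15, 0.16]), "test")
        out = symmetrize_charges(cs, part)
        assert out.charges == pytest.approx([-0.6, 0.15, 0.15, 0.15, 0.15])
        assert out.charges.sum() == pytest.approx(cs.charges.sum(), abs=1e-15)

    def test_idempotent(self, methane):
        part = equivalence_classes(methane)
        cs = ChargeSet(np.array([-0.6, 0.14, 0.15, 0.15, 0.16]), "test")
        once = symmetrize_charges(cs, part)
        twice = symmetrize_charges(once, part)
        assert np.array_equal(once.charges, twice.charges)

    def test_partition_mismatch(self, methane, glycol):
        part = equivalence_classes(glycol)
        with pytest.raises(ChargeError, match="partition"):
            symmetrize_charges(ChargeSet(np.zeros(5), "t"), part)
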