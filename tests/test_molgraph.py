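import numpy as np
import pytest

from conftest import brute_force_bonds
from vibrafrag import (
    CrystalStructure,
    Molecule,
    detect_conjugated_groups,
    dihedral_difference,
    extract_molecules,
    perceive_bonds,
)
from vibrafrag.elements import UnknownElementError
from vibrafrag.errors import PeriodicPolymerError, UndefinedDihedralError
from vibrafrag.molgraph import signed_dihedral


def cell(elements, cart, a=10.0):
    lattice = np.eye(3) * a
    return CrystalStructure(lattice, elements, np.asarray(cart, float) / a)


class TestPerceiveBonds:
    def test_oh_bonded_at_097(self):
        # 0.97 <= r_cov(O) + r_cov(H) + 0.40 = 0.66 + 0.31 + 0.40
        s = cell(["O", "H"], [[1, 1, 1], [1.97, 1, 1]])
        assert (0, 1) in perceive_bonds(s).edges

    def test_oo_not_bonded_at_280(self):
        # 2.80 > 0.66 + 0.66 + 0.40
        s = cell(["O", "O"], [[1, 1, 1], [3.8, 1, 1]])
        assert perceive_bonds(s).edges == {}

    def test_bond_via_image_shift(self):
        # only the periodic image at 0.95 Å is within range
        s = CrystalStructure(np.eye(3) * 10, ["C", "C"],
                             np.array([[0.0, 0.1, 0.1], [0.905, 0.1, 0.1]]))
        g = perceive_bonds(s)
        assert (0, 1) in g.edges
        shift = np.array(g.edges[(0, 1)])
        d = np.linalg.norm((s.frac_coords[1] + shift - s.frac_coords[0]) @ s.lattice)
        assert d == pytest.approx(0.95)
        assert shift[0] != 0

    def test_hh_excluded(self):
        s = cell(["H", "H"], [[1, 1, 1], [1.7, 1, 1]])
        assert perceive_bonds(s).edges == {}

    def test_unknown_element(self):
        s = cell(["Xx", "H"], [[1, 1, 1], [2, 1, 1]])
        with pytest.raises(UnknownElementError, match="Xx"):
            perceive_bonds(s)

    @pytest.mark.parametrize("fixture", ["hf_chain", "water_sheet", "ethanol_dimer"])
    def test_matches_brute_force_oracle(self, fixture, request):
        structure, _ = request.getfixturevalue(fixture)
        assert structure.n_sites <= 200
        g = perceive_bonds(structure)
        oracle = brute_force_bonds(structure)
        assert sorted(g.edges) == sorted(oracle)


class TestExtractMolecules:
    def test_two_separated_waters(self):
        atoms = [[1, 1, 1], [1.96, 1, 1], [1, 1.96, 1],
                 [6, 6, 6], [6.96, 6, 6], [6, 6.96, 6]]
        s = cell(["O", "H", "H"] * 2, [atoms[i] for i in (0, 3, 1, 4, 2, 5)])
        mols = extract_molecules(s, perceive_bonds(s))
        assert [m.n_atoms for m in mols] == [3, 3]
        assert {m.formula for m in mols} == {"H2O"}

    def test_unwrap_across_cell_face(self):
        # water straddling the a face: O at x=9.8, H at x=0.36 (image)
        s = CrystalStructure(np.eye(3) * 10, ["O", "H", "H"],
                             np.array([[0.98, 0.1, 0.1], [0.036, 0.1, 0.1],
                                       [0.98, 0.196, 0.1]]))
        mols = extract_molecules(s, perceive_bonds(s))
        assert len(mols) == 1
        m = mols[0]
        for (a, b) in m.bonds:
            assert np.linalg.norm(m.coords[a] - m.coords[b]) < 2.0

    def test_empty_structure(self):
        s = CrystalStructure(np.eye(3) * 10, [], np.empty((0, 3)))
        assert extract_molecules(s, perceive_bonds(s)) == []

    def test_periodic_polymer_rejected(self):
        # carbon chain continuing through the cell boundary
        s = CrystalStructure(np.diag([4.5, 10, 10]), ["C", "C", "C"],
                             np.array([[0.0, 0.1, 0.1], [1.5 / 4.5, 0.1, 0.1],
                                       [3.0 / 4.5, 0.1, 0.1]]))
        with pytest.raises(PeriodicPolymerError):
            extract_molecules(s, perceive_bonds(s))

    def test_partition_property(self, formamide_sheet):
        structure, _ = formamide_sheet
        mols = extract_molecules(structure, perceive_bonds(structure))
        assert sum(m.n_atoms for m in mols) == structure.n_sites
        covered = sorted(i for m in mols for i in m.site_indices)
        assert covered == list(range(structure.n_sites))

    def test_wrap_invariance(self, water_sheet):
        structure, _ = water_sheet
        mols_a = extract_molecules(structure, perceive_bonds(structure))
        shifted = CrystalStructure(structure.lattice, list(structure.elements),
                                   (structure.frac_coords + [0.37, 0.61, 0.23]) % 1.0)
        mols_b = extract_molecules(shifted, perceive_bonds(shifted))
        assert len(mols_a) == len(mols_b)
        assert sorted(m.formula for m in mols_a) == sorted(m.formula for m in mols_b)
        # internal geometry is translation-invariant: compare sorted bond lengths
        def blens(mols):
            return sorted(round(float(np.linalg.norm(m.coords[a] - m.coords[b])), 6)
                          for m in mols for (a, b) in m.bonds)
        assert blens(mols_a) == blens(mols_b)


def chain_with_dihedral(angle_deg):
    """4-atom chain with unit bond lengths and the given signed dihedral."""
    phi = np.radians(angle_deg)
    theta = np.radians(70.0)   # bend at each inner atom
    p0 = np.array([np.sin(theta), 0.0, np.cos(theta)])
    p1 = np.array([0.0, 0.0, 0.0])
    p2 = np.array([0.0, 0.0, 1.0])
    # bend theta away from the p1->p2 axis; azimuth -phi gives IUPAC dihedral +phi
    p3 = p2 + np.array([np.sin(theta) * np.cos(phi),
                        -np.sin(theta) * np.sin(phi),
                        np.cos(theta)])
    return np.array([p0, p1, p2, p3])


def mol_from_coords(coords):
    n = len(coords)
    return Molecule(list(range(n)), ["C"] * n, coords,
                    [(i, i + 1) for i in range(n - 1)])


class TestDihedrals:
    def test_constructed_chain_has_requested_dihedral(self):
        for target in (180.0, 60.0, 10.0, -10.0):
            c = chain_with_dihedral(target)
            got = signed_dihedral(*c)
            folded = ((got - target) + 180) % 360 - 180
            assert abs(folded) < 1e-8

    def test_identical_molecules_zero(self):
        m = mol_from_coords(chain_with_dihedral(47.0))
        assert dihedral_difference(m, m, (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_anti_vs_gauche_is_120(self):
        a = mol_from_coords(chain_with_dihedral(180.0))
        b = mol_from_coords(chain_with_dihedral(60.0))
        assert dihedral_difference(a, b, (0, 1, 2, 3)) == pytest.approx(120.0, abs=1e-8)

    def test_fold_rule_10_vs_350(self):
        a = mol_from_coords(chain_with_dihedral(10.0))
        b = mol_from_coords(chain_with_dihedral(350.0))
        assert dihedral_difference(a, b, (0, 1, 2, 3)) == pytest.approx(20.0, abs=1e-8)

    def test_collinear_center_raises(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], float)
        m = mol_from_coords(coords)
        with pytest.raises(UndefinedDihedralError):
            dihedral_difference(m, m, (0, 1, 2, 3))


class TestConjugation:
    def test_benzene_ring_one_group(self):
        angles = np.radians(np.arange(6) * 60.0)
        r_c = 1.39
        ring = np.stack([r_c * np.cos(angles), r_c * np.sin(angles),
                         np.zeros(6)], axis=1)
        hs = ring * (1.0 + 1.09 / r_c)
        coords = np.vstack([ring, hs])
        bonds = [(i, (i + 1) % 6) for i in range(6)] + [(i, i + 6) for i in range(6)]
        m = Molecule(list(range(12)), ["C"] * 6 + ["H"] * 6, coords,
                     [(min(a, b), max(a, b)) for a, b in bonds])
        groups = detect_conjugated_groups(m)
        assert len(groups) == 1
        assert groups[0] == set(range(6))

    def test_ethane_no_groups(self):
        m = Molecule([0, 1], ["C", "C"], np.array([[0, 0, 0], [1.54, 0, 0.0]]),
                     [(0, 1)])
        assert detect_conjugated_groups(m) == []

    def test_amide_group_is_ocn(self):
        coords = np.array([[0, 0, 0], [1.23, 0, 0],
                           [-0.675, 1.169, 0], [-1.5, 1.9, 0]])
        m = Molecule([0, 1, 2, 3], ["C", "O", "N", "H"], coords,
                     [(0, 1), (0, 2), (2, 3)])
        groups = detect_conjugated_groups(m)
        assert groups == [{0, 1, 2}]
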