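import numpy as np
import pytest

from vibrafrag import (
    CrystalStructure,
    InterceptionRule,
    build_repeating_unit,
    build_single_molecule,
    central_molecule_auto,
    extract_central_molecule,
    extract_molecules,
    intercept_fragment,
    perceive_bonds,
)
from vibrafrag.cluster_models import ClusterModel
from vibrafrag.crystal_io import FiniteGeometry
from vibrafrag.errors import (
    ConjugationCutError,
    IncompleteShellError,
    InvalidArgumentError,
)


def unit_for(fixture_pair, central=None):
    structure, truth = fixture_pair
    mols = extract_molecules(structure, perceive_bonds(structure))
    if central is None:
        central = central_molecule_auto(structure, mols)
    return build_repeating_unit(structure, central, truth.hbond_criteria)


class TestSingle:
    def test_one_molecule_cell(self, ethanol_dimer):
        structure, _ = ethanol_dimer
        cm = build_single_molecule(structure, 0)
        assert cm.model_kind == "single"
        assert set(cm.atom_roles) == {"central"}
        assert cm.n_atoms == 9

    def test_exact_molecule_atoms(self, hf_chain):
        structure, _ = hf_chain
        mols = extract_molecules(structure, perceive_bonds(structure))
        cm = build_single_molecule(structure, 2, mols)
        assert sorted(cm.site_indices) == sorted(mols[2].site_indices)
        assert np.allclose(cm.geometry.coords, mols[2].coords)

    def test_index_out_of_range(self, hf_chain):
        structure, _ = hf_chain
        with pytest.raises(InvalidArgumentError):
            build_single_molecule(structure, 99)


class TestRepeatingUnit:
    def test_hf_interior_three_molecules(self, hf_chain):
        structure, truth = hf_chain
        cm = build_repeating_unit(structure, 2, truth.hbond_criteria)
        assert cm.model_kind == "repeating_unit"
        assert len(cm.source_molecules) == 3
        assert cm.source_molecules[0] == 2
        roles = {r for r in cm.atom_roles}
        assert roles == {"central", "neighbor"}

    def test_isolated_molecule_warns(self):
        # lone water in a large box: no partners
        lattice = np.eye(3) * 12
        frac = np.array([[0.5, 0.5, 0.5], [0.58, 0.5, 0.5], [0.5, 0.58, 0.5]])
        s = CrystalStructure(lattice, ["O", "H", "H"], frac)
        with pytest.warns(UserWarning, match="no intermolecular hydrogen bonds"):
            cm = build_repeating_unit(s, 0)
        assert len(cm.source_molecules) == 1
        assert set(cm.atom_roles) == {"central"}

    def test_boundary_molecule_rejected(self, hf_chain):
        structure, truth = hf_chain
        with pytest.raises(IncompleteShellError, match="larger supercell"):
            build_repeating_unit(structure, 0, truth.hbond_criteria)


class TestCentral:
    def test_extraction_is_central_subset(self, formamide_sheet):
        unit = unit_for(formamide_sheet)
        central = extract_central_molecule(unit)
        keep = unit.central_atom_indices()
        assert central.model_kind == "central"
        assert np.array_equal(central.geometry.coords, unit.geometry.coords[keep])
        assert central.site_indices == [unit.site_indices[i] for i in keep]

    def test_single_molecule_cluster_identity(self, ethanol_dimer):
        structure, _ = ethanol_dimer
        cm = build_single_molecule(structure, 0)
        again = extract_central_molecule(cm)
        assert np.array_equal(again.geometry.coords, cm.geometry.coords)

    def test_commutes_with_rigid_rotation(self, formamide_sheet):
        unit = unit_for(formamide_sheet)
        theta = np.radians(33.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rotated = unit.with_coords(unit.geometry.coords @ rot.T)
        a = extract_central_molecule(rotated).geometry.coords
        b = extract_central_molecule(unit).geometry.coords @ rot.T
        assert np.allclose(a, b, atol=1e-12)


class TestInterception:
    def test_infinite_radius_is_identity(self, formamide_sheet):
        unit = unit_for(formamide_sheet)
        frag = intercept_fragment(unit, InterceptionRule(radius=np.inf))
        assert frag.n_atoms == unit.n_atoms
        assert "cap" not in frag.atom_roles

    def test_zero_radius_no_flags_keeps_central_only(self, formamide_sheet):
        unit = unit_for(formamide_sheet)
        frag = intercept_fragment(unit, InterceptionRule(
            radius=0.0, keep_hbond_groups=False, keep_conjugated_extensions=False))
        assert set(frag.atom_roles) == {"central"}
        assert frag.n_atoms == len(unit.central_atom_indices())

    def test_ethanol_hbond_group_retention(self, ethanol_dimer):
        """Neighbor donating O-H keeps hydroxyl + alpha-CH2; severed C-C capped."""
        structure, truth = ethanol_dimer
        mols = extract_molecules(structure, perceive_bonds(structure))
        # central = acceptor molecule (the one containing the H-bond acceptor O)
        acc_site = truth.hbonds[0][2]
        central = next(i for i, m in enumerate(mols) if acc_site in m.site_indices)
        unit = build_repeating_unit(structure, central, truth.hbond_criteria)
        frag = intercept_fragment(unit, InterceptionRule(
            radius=0.0, keep_hbond_groups=True, keep_conjugated_extensions=False))
        kept_roles = list(zip(frag.geometry.elements, frag.atom_roles))
        n_caps = frag.atom_roles.count("cap")
        assert n_caps == 1
        neighbor_atoms = [el for el, r in kept_roles if r == "neighbor"]
        # hydroxyl O + its H + alpha carbon + its two hydrogens
        assert sorted(neighbor_atoms) == ["C", "H", "H", "H", "O"]
        # brute-force predicate: every neighbor atom kept is O, H(O), C2 or H(C2)
        donor, h, _ = truth.hbonds[0]
        donor_mol = next(m for m in mols if donor in m.site_indices)
        local_o = donor_mol.site_indices.index(donor)
        allowed = {donor, h}
        for (a, b) in donor_mol.bonds:
            for x, y in ((a, b), (b, a)):
                if donor_mol.site_indices[x] == donor:
                    allowed.add(donor_mol.site_indices[y])
        for x in list(allowed):
            loc = donor_mol.site_indices.index(x)
            if donor_mol.elements[loc] == "C":
                for (a, b) in donor_mol.bonds:
                    for p, q in ((a, b), (b, a)):
                        if p == loc and donor_mol.elements[q] == "H":
                            allowed.add(donor_mol.site_indices[q])
        kept_neighbor_sites = {s for s, r in zip(frag.site_indices, frag.atom_roles)
                               if r == "neighbor"}
        assert kept_neighbor_sites <= allowed

    def test_cap_geometry(self, ethanol_dimer):
        structure, truth = ethanol_dimer
        mols = extract_molecules(structure, perceive_bonds(structure))
        acc_site = truth.hbonds[0][2]
        central = next(i for i, m in enumerate(mols) if acc_site in m.site_indices)
        unit = build_repeating_unit(structure, central, truth.hbond_criteria)
        frag = intercept_fragment(unit, InterceptionRule(
            radius=0.0, keep_hbond_groups=True, keep_conjugated_extensions=False))
        adj = {}
        for (a, b) in frag.bonds:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        for i, role in enumerate(frag.atom_roles):
            if role != "cap":
                continue
            assert frag.geometry.elements[i] == "H"
            assert len(adj[i]) == 1
            anchor = adj[i][0]
            d = np.linalg.norm(frag.geometry.coords[i] - frag.geometry.coords[anchor])
            expected = InterceptionRule().cap_bond_lengths[frag.geometry.elements[anchor]]
            assert d == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_radius(self, formamide_sheet):
        unit = unit_for(formamide_sheet)
        sizes = []
        for radius in (0.0, 2.0, 4.0, 8.0, np.inf):
            frag = intercept_fragment(unit, InterceptionRule(
                radius=radius, keep_hbond_groups=False,
                keep_conjugated_extensions=False, cap=False))
            sizes.append(frag.n_atoms)
        assert sizes == sorted(sizes)

    def test_idempotent(self, ethanol_dimer):
        structure, truth = ethanol_dimer
        mols = extract_molecules(structure, perceive_bonds(structure))
        acc_site = truth.hbonds[0][2]
        central = next(i for i, m in enumerate(mols) if acc_site in m.site_indices)
        unit = build_repeating_unit(structure, central, truth.hbond_criteria)
        rule = InterceptionRule(radius=0.0, keep_hbond_groups=True,
                                keep_conjugated_extensions=False)
        frag1 = intercept_fragment(unit, rule)
        frag2 = intercept_fragment(frag1, rule)
        assert frag2.n_atoms == frag1.n_atoms
        assert np.allclose(frag2.geometry.coords, frag1.geometry.coords)
        assert frag2.atom_roles == frag1.atom_roles

    def test_cut_through_conjugation_raises(self, formamide_sheet):
        """Retaining only the N side of an amide would sever the conjugated C-N."""
        unit = unit_for(formamide_sheet)
        with pytest.raises(ConjugationCutError, match="enlarge radius"):
            intercept_fragment(unit, InterceptionRule(
                radius=0.0, keep_hbond_groups=True,
                keep_conjugated_extensions=False))

    def test_central_atoms_in_every_model(self, formamide_sheet):
        structure, truth = formamide_sheet
        mols = extract_molecules(structure, perceive_bonds(structure))
        central_idx = central_molecule_auto(structure, mols)
        single = build_single_molecule(structure, central_idx, mols)
        unit = build_repeating_unit(structure, central_idx, truth.hbond_criteria)
        frag = intercept_fragment(unit, InterceptionRule(radius=4.0))
        central_sites = set(single.site_indices)
        assert central_sites <= {s for s, r in zip(unit.site_indices, unit.atom_roles)
                                 if r == "central"} | set()
        frag_central = {s for s, r in zip(frag.site_indices, frag.atom_roles)
                        if r == "central"}
        assert central_sites == frag_central


def test_cluster_invariants():
    geom = FiniteGeometry(["C", "H"], [[0, 0, 0], [1.09, 0, 0]])
    with pytest.raises(InvalidArgumentError):
        ClusterModel(geom, ["neighbor", "neighbor"], [0], "single")
    with pytest.raises(InvalidArgumentError):
        # cap must be hydrogen
        ClusterModel(geom, ["cap", "central"], [0], "fragment")
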