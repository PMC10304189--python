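import numpy as np
import pytest

from vibrafrag import ToyCrystalSpec, make_toy_crystal


@pytest.fixture(scope="session")
def hf_chain():
    return make_toy_crystal(ToyCrystalSpec("hf_chain", reps=(5, 1, 1)))


@pytest.fixture(scope="session")
def water_sheet():
    return make_toy_crystal(ToyCrystalSpec("water_sheet", reps=(4, 2, 1)))


@pytest.fixture(scope="session")
def formamide_sheet():
    return make_toy_crystal(ToyCrystalSpec("formamide_sheet", reps=(5, 1, 1)))


@pytest.fixture(scope="session")
def ethanol_dimer():
    return make_toy_crystal(ToyCrystalSpec("ethanol_dimer_cell"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_bonds(structure, tolerance=0.40):
    """Independent all-pairs × 27-image bond oracle."""
    import itertools

    from vibrafrag.elements import covalent_radius

    lat = structure.lattice
    frac = structure.frac_coords
    n = structure.n_sites
    found = {}
    for i in range(n):
        for j in range(i + 1, n):
            if structure.elements[i] == "H" and structure.elements[j] == "H":
                continue
            best = None
            for shift in itertools.product((-1, 0, 1), repeat=3):
                d = np.linalg.norm((frac[j] + np.array(shift) - frac[i]) @ lat)
                if best is None or d < best[0]:
                    best = (d, shift)
            cutoff = (covalent_radius(structure.elements[i])
                      + covalent_radius(structure.elements[j]) + tolerance)
            if best[0] <= cutoff:
                found[(i, j)] = best[1]
    return found


def brute_force_hbonds(mols, crit):
    """Exhaustive (D, H, A) triplet enumeration oracle."""
    out = []
    atoms = [(mi, ai) for mi, m in enumerate(mols) for ai in range(m.n_atoms)]
    bonded = {(mi, a, b) for mi, m in enumerate(mols)
              for (x, y) in m.bonds for (a, b) in ((x, y), (y, x))}
    for (mi, di) in atoms:
        if mols[mi].elements[di] not in crit.donor_elements:
            continue
        for (mh, hi) in atoms:
            if mh != mi or (mi, di, hi) not in bonded:
                continue
            if mols[mh].elements[hi] != "H":
                continue
            for (ma, ai) in atoms:
                if (ma, ai) == (mi, di):
                    continue
                if mols[ma].elements[ai] not in crit.acceptor_elements:
                    continue
                dpos = mols[mi].coords[di]
                hpos = mols[mh].coords[hi]
                apos = mols[ma].coords[ai]
                d_ha = np.linalg.norm(apos - hpos)
                d_da = np.linalg.norm(apos - dpos)
                v1, v2 = dpos - hpos, apos - hpos
                ang = np.degrees(np.arccos(np.clip(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
                if (d_ha <= crit.max_h_acceptor and d_da <= crit.max_donor_acceptor
                        and ang >= crit.min_angle):
                    out.append(((mi, di), (mh, hi), (ma, ai)))
    return sorted(out)
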