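"""Generate a toy molecular crystal and map its hydrogen-bond network.

Builds a 5-cell chain of formamide-like molecules, perceives covalent bonds
under periodic boundary conditions, extracts whole molecules, and detects
N-H···O=C hydrogen bonds with the default geometric criteria (H···A <= 2.5 Å,
D···A <= 3.5 Å, angle at H >= 120°).
"""

from vibrafrag import (
    ToyCrystalSpec,
    detect_hbonds,
    extract_molecules,
    hbond_adjacency,
    make_toy_crystal,
    perceive_bonds,
)

cell, truth = make_toy_crystal(ToyCrystalSpec("formamide_sheet", reps=(5, 1, 1)))
print(f"supercell: {cell.n_sites} sites, volume {cell.volume:.1f} Å³")

bonds = perceive_bonds(cell)
mols = extract_molecules(cell, bonds)
print(f"molecules: {len(mols)} × {mols[0].formula}")

hbonds = detect_hbonds(mols, truth.hbond_criteria)
print(f"\nhydrogen bonds ({len(hbonds)}):")
for hb in hbonds:
    print(f"  mol {hb.donor_molecule} -> mol {hb.acceptor_molecule}: "
          f"d(H···A) = {hb.d_ha:.2f} Å, d(D···A) = {hb.d_da:.2f} Å, "
          f"angle = {hb.angle_dha:.1f}°")

graph = hbond_adjacency(mols, hbonds)
degrees = dict(graph.degree)
print(f"\nmolecule-level H-bond degrees: {degrees}")
print("interior molecules have two partners (a chain), the ends have one.")
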