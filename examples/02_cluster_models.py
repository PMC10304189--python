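"""Build the three cluster models from a hydrogen-bonded dimer.

The ethanol-like dimer has molecule A donating its O-H to molecule B.
Taking B as the central molecule we build: the single-molecule model (B
alone), the repeating unit (B + A), and the intercepted fragment, where A is
trimmed back to its hydroxyl functional group and the severed C-C bond is
closed with a link hydrogen at 1.09 Å.
"""

from vibrafrag import (
    InterceptionRule,
    ToyCrystalSpec,
    build_repeating_unit,
    build_single_molecule,
    extract_central_molecule,
    extract_molecules,
    intercept_fragment,
    make_toy_crystal,
    perceive_bonds,
)

cell, truth = make_toy_crystal(ToyCrystalSpec("ethanol_dimer_cell"))
mols = extract_molecules(cell, perceive_bonds(cell))

# central molecule = the one holding the H-bond acceptor oxygen
acceptor_site = truth.hbonds[0][2]
central = next(i for i, m in enumerate(mols) if acceptor_site in m.site_indices)

single = build_single_molecule(cell, central, mols)
unit = build_repeating_unit(cell, central, truth.hbond_criteria)
fragment = intercept_fragment(unit, InterceptionRule(
    radius=0.0, keep_hbond_groups=True, keep_conjugated_extensions=False))
central_model = extract_central_molecule(unit)

for model in (single, unit, central_model, fragment):
    roles = {r: model.atom_roles.count(r) for r in ("central", "neighbor", "cap")}
    print(f"{model.model_kind:14s} {model.n_atoms:3d} atoms  "
          f"(central {roles['central']}, neighbor {roles['neighbor']}, "
          f"cap {roles['cap']})")

print("\nThe fragment keeps the donor hydroxyl and its alpha-CH2 so the")
print("O-H···O interaction survives, while the methyl group is replaced by")
print("one cap hydrogen — the valence stays closed, the model stays small.")
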