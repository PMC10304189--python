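"""Construction of the three cluster models used for vibrational simulation.

From a molecular crystal (as a supercell) we build:

* **single** — one molecule extracted from the crystal, nothing else;
* **repeating_unit** — a chosen central molecule plus every molecule sharing
  at least one intermolecular hydrogen bond with it (the minimal H-bonded
  repeating unit), to be optimized as a whole;
* **central** — the central molecule cut back out of the (optimized)
  repeating unit, keeping its in-cluster geometry;
* **fragment** — the repeating unit trimmed to the parts connected to the
  central molecule through hydrogen bonds or conjugation, with every severed
  single covalent bond capped by a link hydrogen.

Atom roles (``central`` / ``neighbor`` / ``cap``) are carried through every
operation; the central molecule is never trimmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import CrystalStructure, FiniteGeometry
from .errors import ConjugationCutError, IncompleteShellError, InvalidArgumentError
from .hbond import HBond, HBondCriteria, detect_hbonds, hbond_adjacency
from .molgraph import Molecule, detect_conjugated_groups, extract_molecules, perceive_bonds

DEFAULT_CAP_LENGTHS = {"C": 1.09, "N": 1.01, "O": 0.96}


@dataclass
class InterceptionRule:
    """How far beyond the central molecule the fragment reaches.

    A neighbor atom is retained iff it is within ``radius`` Å of any
    central-molecule atom, or (``keep_hbond_groups``) belongs to the covalent
    functional group — heavy donor/acceptor atom, its directly bonded
    neighbors and their riding hydrogens — of an H-bond to the central
    molecule, or
    (``keep_conjugated_extensions``) sits in a conjugated group that already
    contains a retained atom. ``cap=False`` switches to whole-molecule
    granularity: a neighbor molecule is kept or dropped in full and nothing
    is capped.
    """

    radius: float = 4.0
    keep_hbond_groups: bool = True
    keep_conjugated_extensions: bool = True
    cap_bond_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CAP_LENGTHS))
    cap: bool = True

    def __post_init__(self):
        if self.radius < 0:
            raise InvalidArgumentError("interception radius must be >= 0")
        if any(v <= 0 for v in self.cap_bond_lengths.values()):
            raise InvalidArgumentError("cap bond lengths must be positive")


@dataclass
class ClusterModel:
    """A finite atom cluster tagged by role, plus the bookkeeping needed to
    parameterize force fields and intercept fragments.

    ``site_indices`` maps cluster atoms back to supercell sites (None for cap
    atoms); ``molecule_of`` gives the source-molecule index per atom (-1 for
    caps); ``bonds`` are cluster-local covalent pairs and ``hbond_contacts``
    cluster-local (donor, H, acceptor) triples.
    """

    geometry: FiniteGeometry
    atom_roles: list[str]
    source_molecules: list[int]
    model_kind: str
    provenance: str = ""
    site_indices: list = field(default_factory=list)
    molecule_of: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    hbond_contacts: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.atom_roles) != self.geometry.n_atoms:
            raise InvalidArgumentError("one role per atom required")
        if "central" not in self.atom_roles:
            raise InvalidArgumentError("a cluster model must contain central atoms")
        for i, role in enumerate(self.atom_roles):
            if role == "cap" and self.geometry.elements[i] != "H":
                raise InvalidArgumentError("cap atoms must be hydrogen")

    @property
    def n_atoms(self) -> int:
        return self.geometry.n_atoms

    def central_atom_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.atom_roles) if r == "central"]

    def with_coords(self, coords: np.ndarray) -> "ClusterModel":
        geom = FiniteGeometry(list(self.geometry.elements), np.asarray(coords, float),
                              self.geometry.masses.copy())
        return ClusterModel(geom, list(self.atom_roles), list(self.source_molecules),
                            self.model_kind, self.provenance, list(self.site_indices),
                            list(self.molecule_of), list(self.bonds),
                            list(self.hbond_contacts))


def _analyze(s: CrystalStructure, crit: HBondCriteria | None):
    bonds = perceive_bonds(s)
    mols = extract_molecules(s, bonds)
    hbonds = detect_hbonds(mols, crit)
    return mols, hbonds


def _assemble(mols: list[Molecule], mol_ids: list[int], roles: dict[int, str],
              hbonds: list[HBond], model_kind: str, provenance: str) -> ClusterModel:
    """Stack whole molecules into one cluster, remapping bonds and H-bonds."""
    local: dict[tuple[int, int], int] = {}
    elements: list[str] = []
    coords: list[np.ndarray] = []
    atom_roles: list[str] = []
    site_indices: list[int] = []
    molecule_of: list[int] = []
    cluster_bonds: list[tuple[int, int]] = []
    for mi in mol_ids:
        mol = mols[mi]
        offset = len(elements)
        for ai in range(mol.n_atoms):
            local[(mi, ai)] = offset + ai
            elements.append(mol.elements[ai])
            coords.append(mol.coords[ai])
            atom_roles.append(roles[mi])
            site_indices.append(mol.site_indices[ai])
            molecule_of.append(mi)
        cluster_bonds.extend((offset + a, offset + b) for (a, b) in mol.bonds)
    contacts = []
    for hb in hbonds:
        refs = (hb.donor, hb.h, hb.acceptor)
        if all(r in local for r in refs):
            contacts.append(tuple(local[r] for r in refs))
    geom = FiniteGeometry(elements, np.array(coords))
    return ClusterModel(geom, atom_roles, list(mol_ids), model_kind, provenance,
                        site_indices, molecule_of, cluster_bonds, contacts)


def build_single_molecule(s: CrystalStructure, mol_index: int,
                          mols: list[Molecule] | None = None) -> ClusterModel:
    """The single-molecule model: one crystal molecule, all atoms central."""
    if mols is None:
        mols, _ = _analyze(s, None)
    if not (0 <= mol_index < len(mols)):
        raise InvalidArgumentError(
            f"molecule index {mol_index} out of range (structure has {len(mols)} molecules)")
    return _assemble(mols, [mol_index], {mol_index: "central"}, [], "single",
                     f"single molecule {mol_index} ({mols[mol_index].formula})")


def _boundary_clearance(s: CrystalStructure, mol: Molecule) -> float:
    """Smallest perpendicular distance from any atom of mol to a cell face."""
    inv = np.linalg.inv(s.lattice)
    frac = mol.coords @ inv
    vol = s.volume
    clearance = np.inf
    for axis in range(3):
        others = [v for i, v in enumerate(s.lattice) if i != axis]
        height = vol / np.linalg.norm(np.cross(others[0], others[1]))
        f = frac[:, axis]
        clearance = min(clearance, float(np.min(f) * height), float((1 - np.max(f)) * height))
    return clearance


def central_molecule_auto(s: CrystalStructure, mols: list[Molecule]) -> int:
    """Default central-molecule choice: centroid nearest the supercell centroid."""
    center = 0.5 * s.lattice.sum(axis=0)
    d = [np.linalg.norm(m.centroid - center) for m in mols]
    return int(np.argmin(d))


def build_repeating_unit(s: CrystalStructure, central_index: int,
                         crit: HBondCriteria | None = None,
                         mols: list[Molecule] | None = None,
                         hbonds: list[HBond] | None = None) -> ClusterModel:
    """Central molecule plus all molecules H-bonded to it (whole molecules).

    Raises :class:`IncompleteShellError` when the central molecule sits closer
    to a supercell face than the donor–acceptor cutoff, because its H-bond
    shell could then be truncated by the boundary.
    """
    crit = crit or HBondCriteria()
    if mols is None or hbonds is None:
        mols, hbonds = _analyze(s, crit)
    if not (0 <= central_index < len(mols)):
        raise InvalidArgumentError(
            f"molecule index {central_index} out of range ({len(mols)} molecules)")
    clearance = _boundary_clearance(s, mols[central_index])
    if clearance < crit.max_donor_acceptor:
        raise IncompleteShellError(
            f"central molecule is {clearance:.2f} Å from the supercell boundary, closer "
            f"than the donor-acceptor cutoff {crit.max_donor_acceptor} Å; "
            "build a larger supercell"
        )
    graph = hbond_adjacency(mols, hbonds)
    partners = sorted(graph.neighbors(central_index))
    if not partners:
        warnings.warn("no intermolecular hydrogen bonds found; repeating unit "
                      "degenerates to a single molecule", stacklevel=2)
    mol_ids = [central_index] + partners
    roles = {central_index: "central", **{p: "neighbor" for p in partners}}
    return _assemble(mols, mol_ids, roles, hbonds, "repeating_unit",
                     f"repeating unit around molecule {central_index}: "
                     f"{1 + len(partners)} molecules")


def extract_central_molecule(c: ClusterModel) -> ClusterModel:
    """Cut the central-tagged atoms out of a cluster, keeping current coordinates."""
    keep = c.central_atom_indices()
    if not keep:
        raise InvalidArgumentError("cluster has no central-tagged atoms")
    remap = {old: new for new, old in enumerate(keep)}
    keep_set = set(keep)
    geom = FiniteGeometry([c.geometry.elements[i] for i in keep], c.geometry.coords[keep],
                          c.geometry.masses[keep])
    bonds = [(remap[a], remap[b]) for (a, b) in c.bonds if a in keep_set and b in keep_set]
    contacts = [tuple(remap[x] for x in t) for t in c.hbond_contacts
                if all(x in keep_set for x in t)]
    central_mols = sorted({c.molecule_of[i] for i in keep})
    return ClusterModel(geom, ["central"] * len(keep), central_mols, "central",
                        c.provenance + " -> central molecule extracted",
                        [c.site_indices[i] for i in keep], [c.molecule_of[i] for i in keep],
                        bonds, contacts)


def _conjugated_groups_local(c: ClusterModel) -> list[set[int]]:
    """Conjugated groups per source molecule, in cluster-local indices."""
    groups: list[set[int]] = []
    for mi in sorted(set(c.molecule_of)):
        idx = [i for i, m in enumerate(c.molecule_of) if m == mi]
        if not idx:
            continue
        remap = {local: k for k, local in enumerate(idx)}
        sub = Molecule(
            site_indices=list(range(len(idx))),
            elements=[c.geometry.elements[i] for i in idx],
            coords=c.geometry.coords[idx],
            bonds=[(remap[a], remap[b]) for (a, b) in c.bonds
                   if a in remap and b in remap],
        )
        back = {k: local for local, k in remap.items()}
        groups.extend({back[x] for x in grp} for grp in detect_conjugated_groups(sub))
    return groups


def intercept_fragment(c: ClusterModel, rule: InterceptionRule | None = None) -> ClusterModel:
    """Trim a repeating unit to the H-bond/conjugation-connected fragment.

    Retention follows the three-clause predicate documented on
    :class:`InterceptionRule`; the retained set is closed under "keep every H
    bonded to a retained heavy atom", and each severed single covalent bond is
    replaced by a cap hydrogen along the cut direction. Cutting through a
    conjugated system raises :class:`ConjugationCutError`. Idempotent: re-
    intercepting a fragment with the same rule returns it unchanged.
    """
    rule = rule or InterceptionRule()
    if c.model_kind not in ("repeating_unit", "fragment"):
        raise InvalidArgumentError("fragment interception expects a repeating unit")
    coords = c.geometry.coords
    central = c.central_atom_indices()
    central_coords = coords[central]
    adj: dict[int, list[int]] = {i: [] for i in range(c.n_atoms)}
    for (a, b) in c.bonds:
        adj[a].append(b)
        adj[b].append(a)

    retained: set[int] = set(central)
    retained.update(i for i, r in enumerate(c.atom_roles) if r == "cap")

    if not rule.cap:
        # Whole-molecule granularity: keep a neighbor molecule if any of its
        # atoms is inside the radius or it H-bonds to the central molecule.
        keep_mols = {c.molecule_of[i] for i in central}
        for mi in sorted(set(c.molecule_of) - keep_mols - {-1}):
            idx = [i for i, m in enumerate(c.molecule_of) if m == mi]
            dmin = np.min(np.linalg.norm(
                coords[idx][:, None, :] - central_coords[None, :, :], axis=2))
            has_hb = False
            for (d, h, a) in c.hbond_contacts:
                ends = {c.atom_roles[d], c.atom_roles[a]}
                mols_involved = {c.molecule_of[d], c.molecule_of[a]}
                if "central" in ends and mi in mols_involved:
                    has_hb = True
            if dmin <= rule.radius or (rule.keep_hbond_groups and has_hb):
                retained.update(idx)
    else:
        neighbor_idx = [i for i, r in enumerate(c.atom_roles) if r == "neighbor"]
        if neighbor_idx:
            d = np.linalg.norm(
                coords[neighbor_idx][:, None, :] - central_coords[None, :, :], axis=2)
            within = np.min(d, axis=1) <= rule.radius
            retained.update(i for i, w in zip(neighbor_idx, within) if w)
        if rule.keep_hbond_groups:
            for (d, h, a) in c.hbond_contacts:
                droles, aroles = c.atom_roles[d], c.atom_roles[a]
                if "central" not in (droles, aroles) or droles == aroles:
                    continue
                anchors = [d, h] if droles != "central" else [a]
                heavy = d if droles != "central" else a
                retained.update(anchors)
                # the covalent functional group: heavy anchor plus its direct
                # neighbors (their hydrogens follow via the H closure below)
                retained.update(adj[heavy])
        if rule.keep_conjugated_extensions:
            for grp in _conjugated_groups_local(c):
                if grp & retained:
                    retained.update(grp)
        # closure: hydrogens riding on retained heavy atoms
        changed = True
        while changed:
            changed = False
            for i in list(retained):
                for nb in adj[i]:
                    if c.geometry.elements[nb] == "H" and nb not in retained:
                        retained.add(nb)
                        changed = True

    retained_sorted = sorted(retained)
    remap = {old: new for new, old in enumerate(retained_sorted)}
    elements = [c.geometry.elements[i] for i in retained_sorted]
    new_coords = [coords[i] for i in retained_sorted]
    roles = [c.atom_roles[i] for i in retained_sorted]
    sites = [c.site_indices[i] for i in retained_sorted]
    mol_of = [c.molecule_of[i] for i in retained_sorted]
    new_bonds = [(remap[a], remap[b]) for (a, b) in c.bonds
                 if a in retained and b in retained]
    contacts = [tuple(remap[x] for x in t) for t in c.hbond_contacts
                if all(x in retained for x in t)]

    conj_groups = _conjugated_groups_local(c)
    n_caps = 0
    if rule.cap:
        for (a, b) in c.bonds:
            ra, rb = a in retained, b in retained
            if ra == rb:
                continue
            keep_atom, cut_atom = (a, b) if ra else (b, a)
            for grp in conj_groups:
                if keep_atom in grp and cut_atom in grp:
                    raise ConjugationCutError(
                        f"severed bond {keep_atom}-{cut_atom} lies inside a conjugated "
                        "system; cut through conjugated system; enlarge radius")
            r_el = c.geometry.elements[keep_atom]
            cap_len = rule.cap_bond_lengths.get(r_el, 1.09)
            direction = coords[cut_atom] - coords[keep_atom]
            direction = direction / np.linalg.norm(direction)
            cap_pos = coords[keep_atom] + cap_len * direction
            cap_local = len(elements)
            elements.append("H")
            new_coords.append(cap_pos)
            roles.append("cap")
            sites.append(None)
            mol_of.append(-1)
            new_bonds.append((remap[keep_atom], cap_local))
            n_caps += 1

    geom = FiniteGeometry(elements, np.array(new_coords))
    mol_ids = sorted({m for m in mol_of if m >= 0})
    return ClusterModel(geom, roles, mol_ids, "fragment",
                        c.provenance + f" -> fragment (radius {rule.radius} Å, "
                        f"{len(retained_sorted)} atoms kept, {n_caps} caps)",
                        sites, mol_of, sorted(new_bonds), contacts)
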