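"""Geometric hydrogen-bond detection and the molecule-level H-bond network.

A contact D–H···A qualifies when d(H···A) ≤ max_h_acceptor, d(D···A) ≤
max_donor_acceptor and the angle at H is ≥ min_angle, with D drawn from the
donor element set and A from the acceptor set. Defaults (2.5 Å / 3.5 Å /
120°, D ∈ {N,O}, A ∈ {N,O,S}) follow common crystallographic practice; all
are user-overridable, and every passing triplet is reported (bifurcated
H-bonds are not pruned).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InvalidArgumentError
from .molgraph import Molecule

#: (molecule index, molecule-local atom index)
AtomRef = tuple[int, int]


@dataclass
class HBondCriteria:
    max_h_acceptor: float = 2.5          # Å
    max_donor_acceptor: float = 3.5      # Å
    min_angle: float = 120.0             # degrees at H
    donor_elements: frozenset = frozenset({"N", "O"})
    acceptor_elements: frozenset = frozenset({"N", "O", "S"})

    def __post_init__(self):
        if self.max_h_acceptor <= 0 or self.max_donor_acceptor <= 0:
            raise InvalidArgumentError("H-bond distance cutoffs must be positive")
        if not (0 < self.min_angle <= 180):
            raise InvalidArgumentError("min_angle must lie in (0, 180]")
        self.donor_elements = frozenset(self.donor_elements)
        self.acceptor_elements = frozenset(self.acceptor_elements)


@dataclass
class HBond:
    donor: AtomRef
    h: AtomRef
    acceptor: AtomRef
    d_ha: float
    d_da: float
    angle_dha: float

    @property
    def donor_molecule(self) -> int:
        return self.donor[0]

    @property
    def acceptor_molecule(self) -> int:
        return self.acceptor[0]

    @property
    def intramolecular(self) -> bool:
        return self.donor_molecule == self.acceptor_molecule


def detect_hbonds(mols: list[Molecule], crit: HBondCriteria | None = None) -> list[HBond]:
    """Test every covalent D–H against every acceptor atom in one shared frame.

    Molecules must already sit in one unwrapped Cartesian frame (e.g. an
    unwrapped supercell); no periodic images are considered here.
    """
    crit = crit or HBondCriteria()
    donors: list[tuple[AtomRef, AtomRef]] = []     # (D, H) pairs
    acceptors: list[AtomRef] = []
    for mi, mol in enumerate(mols):
        for (a, b) in mol.bonds:
            for d, h in ((a, b), (b, a)):
                if mol.elements[d] in crit.donor_elements and mol.elements[h] == "H":
                    donors.append(((mi, d), (mi, h)))
        for ai, el in enumerate(mol.elements):
            if el in crit.acceptor_elements:
                acceptors.append((mi, ai))

    def pos(ref: AtomRef) -> np.ndarray:
        return mols[ref[0]].coords[ref[1]]

    out: list[HBond] = []
    for (dref, href) in donors:
        dpos, hpos = pos(dref), pos(href)
        for aref in acceptors:
            if aref == dref:
                continue
            apos = pos(aref)
            d_ha = float(np.linalg.norm(apos - hpos))
            if d_ha > crit.max_h_acceptor:
                continue
            d_da = float(np.linalg.norm(apos - dpos))
            if d_da > crit.max_donor_acceptor:
                continue
            v1 = dpos - hpos
            v2 = apos - hpos
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < crit.min_angle:
                continue
            out.append(HBond(dref, href, aref, d_ha, d_da, angle))
    out.sort(key=lambda hb: (hb.donor_molecule, hb.d_ha, hb.acceptor))
    return out


def hbond_adjacency(mols: list[Molecule], hbonds: list[HBond]) -> nx.Graph:
    """Undirected molecule-level graph; edge weight = number of intermolecular H-bonds."""
    g = nx.Graph()
    g.add_nodes_from(range(len(mols)))
    for hb in hbonds:
        if hb.intramolecular:
            continue
        a, b = hb.donor_molecule, hb.acceptor_molecule
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    return g
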