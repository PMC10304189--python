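"""Covalent bond perception under periodic boundaries, molecule extraction,
unwrapping, and conformation comparison.

Bonds are perceived geometrically: sites i, j are bonded iff their
minimum-image distance is at most r_cov(i) + r_cov(j) + tolerance (default
0.40 Å), H–H pairs excluded. Molecules are connected components of that graph,
unwrapped by a breadth-first walk that accumulates lattice-image shifts so
every bond is realized without wrapping; a component that closes on itself at
a different net shift is an infinite polymer and is rejected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import CrystalStructure
from .elements import covalent_radius
from .errors import InvalidArgumentError, PeriodicPolymerError, UndefinedDihedralError

DEFAULT_BOND_TOLERANCE = 0.40

#: Element-pair distance thresholds (Å) below which a bond counts as
#: unsaturated for the geometric conjugation flag. Pairs are unordered.
UNSATURATED_THRESHOLDS: dict[frozenset, float] = {
    frozenset(["C"]): 1.45,
    frozenset(["C", "N"]): 1.40,
    frozenset(["C", "O"]): 1.30,
    frozenset(["C", "S"]): 1.72,
    frozenset(["N"]): 1.35,
    frozenset(["N", "O"]): 1.30,
    frozenset(["O"]): 1.35,
}

_IMAGE_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


@dataclass
class BondGraph:
    """Covalent bonds as unordered site-index pairs with realizing image shifts.

    ``edges[(i, j)] = (si, sj, sk)`` means site j translated by that lattice
    image is within bonding distance of site i (i < j).
    """

    n_sites: int
    edges: dict[tuple[int, int], tuple[int, int, int]] = field(default_factory=dict)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_sites)]
        for (a, b) in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass
class Molecule:
    """A connected covalent component with unwrapped Cartesian coordinates."""

    site_indices: list[int]             # into the parent structure
    elements: list[str]
    coords: np.ndarray                  # (n, 3) unwrapped Å
    bonds: list[tuple[int, int]]        # molecule-local index pairs
    formula: str = ""
    centroid: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not self.formula:
            self.formula = hill_formula(self.elements)
        if self.centroid is None:
            self.centroid = self.coords.mean(axis=0)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def hill_formula(elements: list[str]) -> str:
    counts: dict[str, int] = {}
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
    parts = []
    for el in ["C", "H"]:
        if el in counts:
            n = counts.pop(el)
            parts.append(el + (str(n) if n > 1 else ""))
    for el in sorted(counts):
        n = counts[el]
        parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def perceive_bonds(s: CrystalStructure, tolerance: float = DEFAULT_BOND_TOLERANCE) -> BondGraph:
    """All-pairs minimum-image bond perception over the 27 neighbor images."""
    if tolerance < 0:
        raise InvalidArgumentError("bond tolerance must be >= 0")
    n = s.n_sites
    graph = BondGraph(n_sites=n)
    if n == 0:
        return graph
    radii = np.array([covalent_radius(el) for el in s.elements])
    frac = s.frac_coords
    lat = s.lattice
    shift_cart = _IMAGE_SHIFTS @ lat       # (27, 3)
    for i in range(n):
        dfrac = frac[i + 1:] - frac[i]     # (m, 3)
        if len(dfrac) == 0:
            continue
        cart = dfrac @ lat                 # (m, 3)
        # distance of each pair under each of the 27 images
        d = np.linalg.norm(cart[:, None, :] + shift_cart[None, :, :], axis=2)  # (m, 27)
        best = np.argmin(d, axis=1)
        dmin = d[np.arange(len(dfrac)), best]
        cutoffs = radii[i] + radii[i + 1:] + tolerance
        for m in np.nonzero(dmin <= cutoffs)[0]:
            j = i + 1 + int(m)
            if s.elements[i] == "H" and s.elements[j] == "H":
                continue
            graph.edges[(i, j)] = tuple(int(x) for x in _IMAGE_SHIFTS[best[m]])
    return graph


def extract_molecules(s: CrystalStructure, g: BondGraph) -> list[Molecule]:
    """Connected components of the bond graph, unwrapped into one coordinate frame.

    The lowest site index of each component is anchored at image shift
    (0,0,0); shifts accumulate along a breadth-first traversal. Molecules are
    returned sorted by (formula, centroid) for determinism.
    """
    n = s.n_sites
    if n == 0:
        return []
    adj: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(n)}
    for (a, b), shift in g.edges.items():
        sh = np.array(shift, dtype=float)
        adj[a].append((b, sh))
        adj[b].append((a, -sh))

    seen: dict[int, np.ndarray] = {}
    molecules = []
    for start in range(n):
        if start in seen:
            continue
        shifts = {start: np.zeros(3)}
        queue = [start]
        while queue:
            cur = queue.pop(0)
            for nb, sh in adj[cur]:
                net = shifts[cur] + sh
                if nb in shifts:
                    if not np.allclose(shifts[nb], net):
                        raise PeriodicPolymerError(
                            "connected component wraps around the cell: "
                            "periodic polymer, not a molecular crystal"
                        )
                else:
                    shifts[nb] = net
                    queue.append(nb)
        members = sorted(shifts)
        local = {site: k for k, site in enumerate(members)}
        coords = np.array([
            (s.frac_coords[site] + shifts[site]) @ s.lattice for site in members
        ])
        bonds = sorted(
            (min(local[a], local[b]), max(local[a], local[b]))
            for (a, b) in g.edges if a in shifts and b in shifts
        )
        molecules.append(Molecule(members, [s.elements[i] for i in members], coords, bonds))
        seen.update(shifts)
    molecules.sort(key=lambda m: (m.formula, tuple(np.round(m.centroid, 6))))
    return molecules


# ---------------------------------------------------------------------------
# Conformation comparison
# ---------------------------------------------------------------------------

def signed_dihedral(p0, p1, p2, p3) -> float:
    """IUPAC right-hand-rule dihedral in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise UndefinedDihedralError("central three atoms are collinear; dihedral undefined")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def dihedral_difference(a: Molecule, b: Molecule, quad: tuple[int, int, int, int]) -> float:
    """|Δ| of the signed dihedral over the same atom quad, folded to [0°, 180°]."""
    for idx in quad:
        if not (0 <= idx < a.n_atoms and 0 <= idx < b.n_atoms):
            raise InvalidArgumentError(f"dihedral atom index {idx} out of range")
    da = signed_dihedral(*(a.coords[i] for i in quad))
    db = signed_dihedral(*(b.coords[i] for i in quad))
    diff = abs(da - db) % 360.0
    return min(diff, 360.0 - diff)


def detect_conjugated_groups(m: Molecule) -> list[set[int]]:
    """Maximal connected sets of geometrically unsaturated (sp²/sp-like) atoms.

    An atom is flagged if it participates in a bond shorter than the
    single-bond threshold for its element pair, or if it is O/N covalently
    bonded to a flagged atom (captures amide/carboxyl delocalization).
    """
    flagged: set[int] = set()
    for (i, j) in m.bonds:
        key = frozenset([m.elements[i], m.elements[j]])
        thr = UNSATURATED_THRESHOLDS.get(key)
        if thr is not None and np.linalg.norm(m.coords[i] - m.coords[j]) < thr:
            flagged.update((i, j))
    for (i, j) in m.bonds:
        if m.elements[i] in ("O", "N") and j in flagged:
            flagged.add(i)
        if m.elements[j] in ("O", "N") and i in flagged:
            flagged.add(j)
    # connected components within the flagged set
    groups: list[set[int]] = []
    remaining = set(flagged)
    adj: dict[int, set[int]] = {i: set() for i in flagged}
    for (i, j) in m.bonds:
        if i in flagged and j in flagged:
            adj[i].add(j)
            adj[j].add(i)
    while remaining:
        start = min(remaining)
        comp = {start}
        queue = [start]
        while queue:
            cur = queue.pop()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        groups.append(comp)
        remaining -= comp
    groups.sort(key=min)
    return groups
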