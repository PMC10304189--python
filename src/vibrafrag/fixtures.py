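"""Synthetic toy crystals with ground truth, and packaged benchmark tables.

The toy-crystal generator emulates periodic molecular crystals of small
hydrogen-bond donor/acceptor molecules at idealized geometry: every covalent
bond and angle sits exactly at the reference value recorded in the
accompanying toy-force-field parameters, so the noise-free structure is an
exact analytic minimum. Donor X–H bonds are built 0.02 Å longer than their
gas-phase reference length — the characteristic elongation a hydrogen bond
imposes on its donor — which is what lets an isolated-molecule model relax
away from the in-crystal geometry.

Packaged tables FIN_t1 … REP_t3 are published benchmark IR assignments for
finasteride (FIN), lamivudine (LAM) and repaglinide (REP): observed band
positions with wavenumbers calculated from a single-molecule DFT model (t1),
a central-molecule model (t2) and a multi-molecular H-bonded fragment model
(t3), vendored row-for-row as printed (including a scaled column that is not
everywhere consistent with its nominal 0.99 factor; see the t1 LAM 1041.08
row and the whole REP scaled column).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backends import ToyForceFieldParams, parameterize
from .crystal_io import CrystalStructure, FiniteGeometry, build_supercell
from .errors import InvalidArgumentError
from .hbond import HBondCriteria
from .spectra import AssignmentTable, assign_groups

#: extra length (Å) a donor X–H carries in-crystal relative to gas phase
DONOR_H_ELONGATION = 0.02

TABLE_NAMES = tuple(
    f"{drug}_{t}" for drug in ("FIN", "LAM", "REP") for t in ("t1", "t2", "t3")
)


@dataclass
class ToyCrystalSpec:
    kind: str                       # hf_chain | water_sheet | formamide_sheet | ethanol_dimer_cell
    noise: float = 0.0              # Å Gaussian jitter std
    seed: int = 0
    reps: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        if self.noise < 0:
            raise InvalidArgumentError("noise must be >= 0")


@dataclass
class GroundTruth:
    """What the generator built: ideal geometry, bonds, H-bonds, FF parameters."""

    reference: FiniteGeometry            # supercell site order, unwrapped Å
    bonds: list                         # site-index pairs
    hbonds: list                        # (donor, H, acceptor) site triples
    donor_h_pairs: list                 # donor X–H site pairs (elongated in-crystal)
    molecule_count: int
    gas_shift_delta: float = DONOR_H_ELONGATION
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    _params: ToyForceFieldParams | None = field(default=None, repr=False)

    def params(self) -> ToyForceFieldParams:
        """Toy-FF parameters whose exact minimum is the reference geometry."""
        if self._params is None:
            self._params = parameterize(self.reference, self.bonds, self.hbonds)
        return self._params


def _rot2(v: np.ndarray, deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([v[0] * c - v[1] * s, v[0] * s + v[1] * c, 0.0])


def _unit_hf():
    """One H–F molecule per cell, zigzag H-bonded chain along a."""
    r_fh = 0.92 + DONOR_H_ELONGATION
    d_ha = 1.75
    tilt = 20.0
    h = r_fh * np.array([np.cos(np.radians(tilt)), np.sin(np.radians(tilt)), 0.0])
    a = h[0] + np.sqrt(d_ha**2 - h[1] ** 2)
    lattice = np.diag([a, 6.0, 6.0])
    coords = np.array([[0.0, 0.0, 0.0], h])
    elements = ["F", "H"]
    bonds = [(0, 1)]
    # donor F(0)–H(1) of each cell accepts into F of the next cell along a
    hbond_templates = [(0, 1, 0, (1, 0, 0))]
    donor_pairs = [(0, 1)]
    return lattice, elements, coords, bonds, hbond_templates, donor_pairs


def _unit_water():
    """One water per cell: O–H···O chains along a, rows isolated along b/c."""
    r_oh_donor = 0.96 + DONOR_H_ELONGATION
    d_ha = 1.80
    tilt = 15.0
    h1 = r_oh_donor * np.array([np.cos(np.radians(tilt)), np.sin(np.radians(tilt)), 0.0])
    h2 = 0.96 * _rot2(np.array([1.0, 0.0, 0.0]), tilt + 104.5)
    a = h1[0] + np.sqrt(d_ha**2 - h1[1] ** 2)
    lattice = np.diag([a, 6.0, 6.0])
    coords = np.array([[0.0, 0.0, 0.0], h1, h2])
    elements = ["O", "H", "H"]
    bonds = [(0, 1), (0, 2)]
    hbond_templates = [(0, 1, 0, (1, 0, 0))]
    donor_pairs = [(0, 1)]
    return lattice, elements, coords, bonds, hbond_templates, donor_pairs


def _unit_formamide():
    """One formamide-like molecule per cell: N–H···O=C chains along a.

    The amide group carries conjugated-length C=O and C–N bonds. The
    non-bonded hydrogens are pitched ~18° out of the heavy-atom plane: with
    purely harmonic bond/angle terms an exactly planar center has a flat
    (quartic) pyramidalization direction, which would leave spurious
    near-zero modes in every cluster built from the fixture.
    """
    a_len = 4.8
    c = np.zeros(3)
    o = np.array([1.23, 0.0, 0.0])
    n = 1.35 * np.array([np.cos(np.radians(120)), np.sin(np.radians(120)), 0.0])
    u_hc = np.array([np.cos(np.radians(240)), np.sin(np.radians(240)), 0.33])
    h_c = 1.09 * u_hc / np.linalg.norm(u_hc)
    o_prev = o - np.array([a_len, 0.0, 0.0])
    v = o_prev - n
    u = _rot2(v / np.linalg.norm(v), 12.0)
    h_n1 = n + (1.01 + DONOR_H_ELONGATION) * u
    u2 = _rot2(u, -120.0) + np.array([0.0, 0.0, 0.33])
    h_n2 = n + 1.01 * u2 / np.linalg.norm(u2)
    lattice = np.diag([a_len, 7.0, 6.0])
    coords = np.array([c, o, n, h_n1, h_n2, h_c])
    elements = ["C", "O", "N", "H", "H", "H"]
    bonds = [(0, 1), (0, 2), (0, 5), (2, 3), (2, 4)]
    hbond_templates = [(2, 3, 1, (-1, 0, 0))]     # N–H1 donates to O of previous cell
    donor_pairs = [(2, 3)]
    return lattice, elements, coords, bonds, hbond_templates, donor_pairs


def _tetrahedral_pair(axis: np.ndarray, ref: np.ndarray):
    """Two unit vectors ~109.5° from -axis, symmetric about the axis/ref plane."""
    axis = axis / np.linalg.norm(axis)
    perp = ref - (ref @ axis) * axis
    perp = perp / np.linalg.norm(perp)
    out = np.cross(axis, perp)
    base = -np.cos(np.radians(70.5))
    s = np.sin(np.radians(70.5))
    return (base * axis + s * (np.cos(np.radians(120)) * perp + np.sin(np.radians(120)) * out),
            base * axis + s * (np.cos(np.radians(120)) * perp - np.sin(np.radians(120)) * out))


def _unit_ethanol_dimer():
    """Two ethanol-like molecules in one cell, A donating O–H···O to B.

    Atom order per molecule: C1(methyl), C2, O, H(O), 3×H(C1), 2×H(C2).
    """
    c2 = np.zeros(3)
    o = np.array([1.43, 0.0, 0.0])
    c1 = c2 + 1.54 * np.array([np.cos(np.radians(109.5)), np.sin(np.radians(109.5)), 0.0])
    u_oh = np.array([np.cos(np.radians(-15)), np.sin(np.radians(-15)), 0.0])
    h_o = o + (0.96 + DONOR_H_ELONGATION) * u_oh
    # methyl hydrogens: one anti to C2, two completing the tetrahedron
    ax = (c1 - c2) / np.linalg.norm(c1 - c2)
    h11 = c1 + 1.09 * ax
    d1, d2 = _tetrahedral_pair(-ax, np.array([0.0, 0.0, 1.0]))
    h12 = c1 + 1.09 * d1
    h13 = c1 + 1.09 * d2
    # CH2 hydrogens: in the plane bisecting the C1 and O directions
    u1 = (c1 - c2) / np.linalg.norm(c1 - c2)
    u2 = (o - c2) / np.linalg.norm(o - c2)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    nrm = np.cross(u1, u2)
    nrm /= np.linalg.norm(nrm)
    half = np.radians(109.5 / 2.0)
    h21 = c2 + 1.09 * (np.cos(half) * bis + np.sin(half) * nrm)
    h22 = c2 + 1.09 * (np.cos(half) * bis - np.sin(half) * nrm)
    mol = np.array([c1, c2, o, h_o, h11, h12, h13, h21, h22])
    elements_one = ["C", "C", "O", "H", "H", "H", "H", "H", "H"]
    # molecule B: rotated 90° about z and placed so its O sits 1.80 Å beyond
    # A's hydroxyl H, skeleton extending away from A
    o_b_target = h_o + 1.80 * u_oh
    rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    mol_b = (mol - o) @ rot90.T + o_b_target
    coords = np.vstack([mol, mol_b])
    elements = elements_one * 2
    lattice = np.diag([14.0, 10.0, 10.0])
    bonds_one = [(0, 1), (1, 2), (2, 3), (0, 4), (0, 5), (0, 6), (1, 7), (1, 8)]
    bonds = bonds_one + [(i + 9, j + 9) for (i, j) in bonds_one]
    hbond_templates = [(2, 3, 11, (0, 0, 0))]     # A's O–H donates to B's O
    donor_pairs = [(2, 3)]
    return lattice, elements, coords, bonds, hbond_templates, donor_pairs


_UNITS = {
    "hf_chain": _unit_hf,
    "water_sheet": _unit_water,
    "formamide_sheet": _unit_formamide,
    "ethanol_dimer_cell": _unit_ethanol_dimer,
}


def make_toy_crystal(spec: ToyCrystalSpec) -> tuple[CrystalStructure, GroundTruth]:
    """Deterministic toy crystal + ground truth for the given spec.

    At noise 0 the returned supercell geometry is an exact minimum of
    ``truth.params()``. Noise adds per-site Gaussian jitter (Å, seeded) to
    the structure only — the truth keeps the ideal reference.
    """
    if spec.kind not in _UNITS:
        raise InvalidArgumentError(
            f"unknown toy crystal kind {spec.kind!r}; valid: {sorted(_UNITS)}")
    lattice, elements, coords, unit_bonds, hb_templates, unit_donors = _UNITS[spec.kind]()
    # pad non-chain axes so any interior molecule clears every cell face by
    # more than the default donor-acceptor cutoff (complete-shell check)
    span = coords.max(axis=0) - coords.min(axis=0)
    free_axes = (0, 1, 2) if spec.kind == "ethanol_dimer_cell" else (1, 2)
    margin = np.full(3, 0.8)
    for ax in free_axes:
        lattice[ax, ax] = span[ax] + 7.4
        margin[ax] = 3.7
    shift = margin - coords.min(axis=0)
    coords = coords + shift
    frac = coords @ np.linalg.inv(lattice)
    unit = CrystalStructure(lattice, list(elements), frac,
                            [f"{el}{i+1}" for i, el in enumerate(elements)])
    ra, rb, rc = spec.reps
    cell = build_supercell(unit, spec.reps)

    n_unit = len(elements)

    def img_index(i, j, k):
        return (i * rb + j) * rc + k

    bonds, hbonds, donors = [], [], []
    ref_coords = np.zeros((cell.n_sites, 3))
    for i in range(ra):
        for j in range(rb):
            for k in range(rc):
                off = img_index(i, j, k) * n_unit
                img_shift = np.array([i, j, k], float) @ lattice
                ref_coords[off:off + n_unit] = coords + img_shift
                bonds.extend((off + a, off + b) for (a, b) in unit_bonds)
                donors.extend((off + d, off + h) for (d, h) in unit_donors)
                for (d, h, a, (si, sj, sk)) in hb_templates:
                    ti, tj, tk = i + si, j + sj, k + sk
                    if 0 <= ti < ra and 0 <= tj < rb and 0 <= tk < rc:
                        toff = img_index(ti, tj, tk) * n_unit
                        hbonds.append((off + d, off + h, toff + a))

    n_mols = cell.n_sites // n_unit if spec.kind != "ethanol_dimer_cell" else \
        2 * (cell.n_sites // n_unit)
    reference = FiniteGeometry(list(cell.elements), ref_coords)
    # HF has fluorine donors/acceptors, outside the crystallographic defaults
    crit = (HBondCriteria(donor_elements=frozenset({"N", "O", "F"}),
                          acceptor_elements=frozenset({"N", "O", "S", "F"}))
            if spec.kind == "hf_chain" else HBondCriteria())
    truth = GroundTruth(reference, sorted(bonds), sorted(hbonds), sorted(donors), n_mols,
                        hbond_criteria=crit)

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        jitter = rng.normal(0.0, spec.noise, size=(cell.n_sites, 3))
        noisy_cart = cell.cart_coords + jitter
        cell = CrystalStructure(cell.lattice, list(cell.elements),
                                noisy_cart @ np.linalg.inv(cell.lattice),
                                list(cell.site_labels))
    return cell, truth


def load_reference_table(name: str) -> AssignmentTable:
    """Load one packaged benchmark assignment table (FIN_t1 … REP_t3).

    Rows come back exactly as printed in the source benchmark; FG/NFG tags
    are assigned by the label-based rule in :func:`vibrafrag.spectra.assign_groups`.
    """
    if name not in TABLE_NAMES:
        raise InvalidArgumentError(
            f"unknown table {name!r}; valid names: {', '.join(TABLE_NAMES)}")
    ref = importlib.resources.files("vibrafrag").joinpath("data", "tables", f"{name}.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    table = AssignmentTable.from_frame(df)
    table.group = assign_groups(table.labels)
    return table
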