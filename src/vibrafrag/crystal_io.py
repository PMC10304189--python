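"""Periodic crystal structures and finite geometries: CIF/XYZ I/O and supercells.

Conventions: lattice vectors are the *rows* of ``lattice``; fractional
coordinates live only inside :class:`CrystalStructure` — everything downstream
works in Cartesian Å. The CIF reader supports P1 blocks and blocks with an
explicit symmetry-operator loop (``_symmetry_equiv_pos_as_xyz`` or the
``_space_group_symop`` spelling); named space-group lookup is deliberately out
of scope, so fixture/writer output is always P1 or explicit-operator form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .elements import mass_of
from .errors import InvalidArgumentError, MalformedInputError

#: Two expanded sites closer than this (minimum-image Cartesian Å) are merged.
DUPLICATE_SITE_TOLERANCE = 0.3


@dataclass
class CrystalStructure:
    """A periodic cell: row-vector lattice (Å), per-site symbols and fractional coords."""

    lattice: np.ndarray                 # (3, 3), rows a, b, c in Å
    elements: list[str]
    frac_coords: np.ndarray             # (N, 3), in [0, 1)
    site_labels: list[str] = field(default_factory=list)
    space_group_applied: bool = True

    def __post_init__(self):
        self.lattice = np.asarray(self.lattice, dtype=float)
        self.frac_coords = np.asarray(self.frac_coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.frac_coords):
            raise InvalidArgumentError(
                f"{len(self.elements)} elements but {len(self.frac_coords)} coordinate rows"
            )
        if not self.site_labels:
            self.site_labels = [f"{el}{i+1}" for i, el in enumerate(self.elements)]
        if self.volume <= 0:
            raise InvalidArgumentError("cell volume must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.elements)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.lattice)))

    @property
    def cart_coords(self) -> np.ndarray:
        return self.frac_coords @ self.lattice


@dataclass
class FiniteGeometry:
    """A finite (non-periodic) set of atoms: symbols, Cartesian Å coords, amu masses."""

    elements: list[str]
    coords: np.ndarray                  # (N, 3) Å
    masses: np.ndarray | None = None    # amu; default looked up per element

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.masses is None:
            self.masses = np.array([mass_of(el) for el in self.elements], dtype=float)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if not (len(self.elements) == len(self.coords) == len(self.masses)):
            raise InvalidArgumentError("elements, coords and masses must have equal length")
        if np.any(self.masses <= 0):
            raise InvalidArgumentError("all masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "FiniteGeometry":
        return FiniteGeometry(list(self.elements), self.coords.copy(), self.masses.copy())


# ---------------------------------------------------------------------------
# CIF
# ---------------------------------------------------------------------------

_CELL_TAGS = (
    "_cell_length_a", "_cell_length_b", "_cell_length_c",
    "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma",
)
_SYMOP_TAGS = (
    "_symmetry_equiv_pos_as_xyz",
    "_space_group_symop_operation_xyz",
)


def _cif_number(text: str) -> float:
    # CIF numbers may carry an su in parentheses, e.g. "10.123(4)".
    return float(text.split("(")[0])


def lattice_from_parameters(a, b, c, alpha, beta, gamma) -> np.ndarray:
    cell = gemmi.UnitCell(a, b, c, alpha, beta, gamma)
    # gemmi's orthogonalization matrix has a, b, c as columns.
    return np.array(cell.orth.mat.tolist(), dtype=float).T


def _min_image_dist(lattice: np.ndarray, dfrac: np.ndarray) -> float:
    """Minimum-image Cartesian distance for a fractional difference vector."""
    shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
    cart = (dfrac + shifts) @ lattice
    return float(np.min(np.linalg.norm(cart, axis=1)))


def apply_symmetry(
    lattice: np.ndarray,
    elements: list[str],
    frac_coords: np.ndarray,
    labels: list[str],
    ops: list[gemmi.Op],
    merge_tol: float = DUPLICATE_SITE_TOLERANCE,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Expand sites by symmetry operators, wrap to [0,1) and merge duplicates.

    Idempotent: re-expanding an already-expanded set (with the same operators)
    merges every new image back onto an existing site.
    """
    out_el: list[str] = []
    out_fc: list[np.ndarray] = []
    out_lb: list[str] = []
    for el, fc, lb in zip(elements, frac_coords, labels):
        for op in ops:
            new = np.array(op.apply_to_xyz(list(map(float, fc))), dtype=float) % 1.0
            dup = False
            for existing in out_fc:
                if _min_image_dist(lattice, new - existing) < merge_tol:
                    dup = True
                    break
            if not dup:
                out_el.append(el)
                out_fc.append(new)
                out_lb.append(lb)
    return out_el, np.array(out_fc).reshape(-1, 3), out_lb


def read_cif(path) -> CrystalStructure:
    """Read one crystallographic data block; apply symmetry; merge duplicates.

    Raises :class:`MalformedInputError` naming the missing tag when cell
    parameters are absent, or quoting the operator text when a symmetry
    operator cannot be parsed. Sites with occupancy < 1 are rejected.
    """
    path = Path(path)
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    cell_values = []
    for tag in _CELL_TAGS:
        value = block.find_value(tag)
        if value is None:
            raise MalformedInputError(f"CIF {path.name}: missing required tag {tag}")
        cell_values.append(_cif_number(value))
    lattice = lattice_from_parameters(*cell_values)

    op_texts = None
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        if len(col) > 0:
            op_texts = list(col)
            break
        value = block.find_value(tag)
        if value is not None:
            op_texts = [value]
            break
    if op_texts is None:
        op_texts = ["x,y,z"]
    ops = []
    for text in op_texts:
        clean = gemmi.cif.as_string(text)
        try:
            ops.append(gemmi.Op(clean))
        except (RuntimeError, ValueError) as exc:
            raise MalformedInputError(
                f"CIF {path.name}: unparseable symmetry operator {clean!r}"
            ) from exc

    table = block.find(
        "_atom_site_", ["label", "?type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy"]
    )
    if len(table) == 0:
        raise MalformedInputError(f"CIF {path.name}: missing _atom_site_ loop")
    elements, fracs, labels = [], [], []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        symbol = gemmi.cif.as_string(row[1]) if row.has(1) else ""
        if not symbol:
            symbol = "".join(ch for ch in label if ch.isalpha())[:2]
            # Two-letter guess falls back to one letter for e.g. "C12" vs "Cl2".
            if symbol and symbol[0].upper() + symbol[1:].lower() not in ("Cl", "Br", "Na", "Si",
                                                                        "Fe", "Cu", "Zn", "Mg",
                                                                        "Ca", "Al"):
                symbol = symbol[0]
        if row.has(5):
            occ = _cif_number(gemmi.cif.as_string(row[5]))
            if occ < 1.0 - 1e-6:
                raise MalformedInputError(
                    f"CIF {path.name}: site {label} has occupancy {occ} < 1; "
                    "partially occupied structures are not supported"
                )
        elements.append(symbol)
        fracs.append([_cif_number(gemmi.cif.as_string(row[i])) for i in (2, 3, 4)])
        labels.append(label)

    el, fc, lb = apply_symmetry(lattice, elements, np.array(fracs) % 1.0, labels, ops)
    return CrystalStructure(lattice, el, fc, lb, space_group_applied=True)


def write_cif(s: CrystalStructure, path) -> None:
    """Write a P1 CIF (symmetry already applied)."""
    lat = s.lattice
    a, b, c = (float(np.linalg.norm(lat[i])) for i in range(3))
    alpha = float(np.degrees(np.arccos(lat[1] @ lat[2] / (b * c))))
    beta = float(np.degrees(np.arccos(lat[0] @ lat[2] / (a * c))))
    gamma = float(np.degrees(np.arccos(lat[0] @ lat[1] / (a * b))))
    lines = [
        "data_vibrafrag",
        "_symmetry_space_group_name_H-M   'P 1'",
        f"_cell_length_a   {a:.8f}",
        f"_cell_length_b   {b:.8f}",
        f"_cell_length_c   {c:.8f}",
        f"_cell_angle_alpha   {alpha:.6f}",
        f"_cell_angle_beta   {beta:.6f}",
        f"_cell_angle_gamma   {gamma:.6f}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "  'x,y,z'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for lb, el, fc in zip(s.site_labels, s.elements, s.frac_coords):
        lines.append(f"  {lb} {el} {fc[0]:.8f} {fc[1]:.8f} {fc[2]:.8f} 1.0")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Supercells
# ---------------------------------------------------------------------------

def build_supercell(s: CrystalStructure, reps: tuple[int, int, int]) -> CrystalStructure:
    """Replicate the cell ``reps = (ra, rb, rc)`` times along a, b, c.

    Site ordering is image-major (images in lexicographic (i, j, k) order,
    parent site order within each image), which downstream ground-truth
    bookkeeping relies on.
    """
    ra, rb, rc = (int(r) for r in reps)
    if min(ra, rb, rc) < 1:
        raise InvalidArgumentError(f"supercell reps must all be >= 1, got {reps}")
    new_lattice = s.lattice * np.array([[ra], [rb], [rc]], dtype=float)
    scale = np.array([ra, rb, rc], dtype=float)
    elements, fracs, labels = [], [], []
    for i in range(ra):
        for j in range(rb):
            for k in range(rc):
                shift = np.array([i, j, k], dtype=float)
                for el, fc, lb in zip(s.elements, s.frac_coords, s.site_labels):
                    elements.append(el)
                    fracs.append((fc + shift) / scale)
                    labels.append(f"{lb}_{i}{j}{k}" if (ra, rb, rc) != (1, 1, 1) else lb)
    return CrystalStructure(new_lattice, elements, np.array(fracs), labels,
                            space_group_applied=s.space_group_applied)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(g: FiniteGeometry, path, comment: str = "", roles=None) -> None:
    """Standard XYZ; an optional per-atom role tag is appended as a 5th column."""
    if g.n_atoms == 0:
        raise InvalidArgumentError("refusing to write an empty geometry")
    lines = [str(g.n_atoms), comment.replace("\n", " ")]
    for i, (el, xyz) in enumerate(zip(g.elements, g.coords)):
        line = f"{el} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}"
        if roles is not None:
            line += f" {roles[i]}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> FiniteGeometry:
    text = Path(path).read_text().splitlines()
    if not text:
        raise MalformedInputError(f"XYZ {path}: empty file")
    try:
        count = int(text[0].split()[0])
    except (ValueError, IndexError):
        raise MalformedInputError(f"XYZ {path}: first line must be the atom count") from None
    body = [ln for ln in text[2:] if ln.strip()]
    if len(body) != count:
        raise MalformedInputError(
            f"XYZ {path}: count line says {count} atoms but body has {len(body)} lines"
        )
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise MalformedInputError(f"XYZ {path}: bad atom line {ln!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return FiniteGeometry(elements, np.array(coords))
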