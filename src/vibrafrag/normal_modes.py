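"""Harmonic vibrational analysis.

Mass-weight the Cartesian Hessian, project out the rigid-body subspace
(3 translations + 3 rotations, 2 for collinear geometries), diagonalize, and
convert eigenvalues to wavenumbers with ν̃ = sign(λ)·√|λ|/(2πc). Imaginary
modes are reported as negative wavenumbers. An empirical scale factor can be
applied to compensate for the systematic overestimation of harmonic
frequencies (0.99 is the conventional choice for GGA/PBE-quality data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import scipy.linalg

from .crystal_io import FiniteGeometry
from .elements import FREQ_CM1_PER_SQRT_EIGVAL
from .errors import InvalidArgumentError

#: |negative wavenumber| beyond which a mode counts as genuinely imaginary.
IMAGINARY_TOLERANCE_CM1 = 1.0

#: Moment-of-inertia ratio below which a geometry is treated as collinear.
LINEARITY_TOLERANCE = 1e-6


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention used on all reported frequencies."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class NormalModeResult:
    """Ascending frequencies (cm⁻¹; negatives = imaginary) with orthonormal
    mass-weighted mode vectors, one row per kept frequency."""

    frequencies: np.ndarray
    modes: np.ndarray                  # (n_modes, 3N), unit norm, mass-weighted
    n_projected: int
    removed_frequencies: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def has_imaginary(self) -> bool:
        return bool(np.any(self.frequencies < -IMAGINARY_TOLERANCE_CM1))

    def rounded(self, ndigits: int = 2) -> np.ndarray:
        return np.array([round_half_up(f, ndigits) for f in self.frequencies])


@dataclass
class ScaleFactor:
    value: float = 0.99
    provenance: str = "conventional harmonic scale factor for GGA/PBE-quality data"

    def __post_init__(self):
        if not (0 < self.value <= 1.2):
            raise InvalidArgumentError(f"scale factor {self.value} outside (0, 1.2]")


def is_collinear(g: FiniteGeometry, tol: float = LINEARITY_TOLERANCE) -> bool:
    com = np.average(g.coords, axis=0, weights=g.masses)
    x = g.coords - com
    inertia = np.zeros((3, 3))
    for m, r in zip(g.masses, x):
        inertia += m * (np.eye(3) * (r @ r) - np.outer(r, r))
    w = np.sort(np.abs(scipy.linalg.eigvalsh(inertia)))
    return bool(w[-1] > 0 and w[0] / w[-1] < tol)


def rigid_body_vectors(g: FiniteGeometry) -> np.ndarray:
    """Orthonormal mass-weighted translation + rotation vectors, (k, 3N)."""
    n = g.n_atoms
    sq = np.sqrt(g.masses)
    com = np.average(g.coords, axis=0, weights=g.masses)
    x = g.coords - com
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sq
        vecs.append(v.reshape(-1))
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        v = (np.cross(x, e) * sq[:, None]).reshape(-1)
        vecs.append(v)
    out = []
    for v in vecs:
        for u in out:
            v = v - (u @ v) * u
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            out.append(v / norm)
    return np.array(out)


def vibrational_analysis(h: np.ndarray, g: FiniteGeometry,
                         project: bool = True) -> NormalModeResult:
    """Frequencies and modes from a Cartesian Hessian in Hartree/Å².

    With ``project`` the rigid-body subspace is removed before
    diagonalization and the corresponding near-zero eigenvalues are dropped
    (their wavenumber magnitudes are kept in ``removed_frequencies``).
    """
    h = np.asarray(h, dtype=float)
    n3 = 3 * g.n_atoms
    if h.shape != (n3, n3):
        raise InvalidArgumentError(f"Hessian shape {h.shape} does not match 3N = {n3}")
    asym = np.max(np.abs(h - h.T))
    if asym > 1e-8:
        raise InvalidArgumentError(
            f"Hessian asymmetric (max |H - Hᵀ| = {asym:.2e}); symmetrize it first")
    if np.any(g.masses <= 0):
        raise InvalidArgumentError("all masses must be positive")

    sq = np.repeat(np.sqrt(g.masses), 3)
    hmw = h / np.outer(sq, sq)

    n_projected = 0
    if project:
        basis = rigid_body_vectors(g)
        n_projected = len(basis)
        proj = np.eye(n3) - basis.T @ basis
        hmw = proj @ hmw @ proj
        hmw = 0.5 * (hmw + hmw.T)

    evals, evecs = scipy.linalg.eigh(hmw)
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * FREQ_CM1_PER_SQRT_EIGVAL

    removed = np.empty(0)
    if project and n_projected:
        drop = np.argsort(np.abs(evals))[:n_projected]
        keep = np.setdiff1d(np.arange(n3), drop)
        removed = np.abs(freqs[drop])
        freqs = freqs[keep]
        evecs = evecs[:, keep]

    order = np.argsort(freqs)
    return NormalModeResult(freqs[order], evecs[:, order].T, n_projected, removed)


def apply_scale_factor(r: NormalModeResult, f: ScaleFactor | float) -> NormalModeResult:
    """Multiply every frequency by the scale factor; ordering is preserved.

    Full precision is kept internally; output surfaces round half-up to two
    decimals via :meth:`NormalModeResult.rounded`.
    """
    factor = f.value if isinstance(f, ScaleFactor) else float(f)
    if isinstance(f, float) or isinstance(f, int):
        ScaleFactor(factor)  # validate range
    return replace(r, frequencies=r.frequencies * factor)


def mode_locality(result: NormalModeResult, atom_indices, n_atoms: int) -> np.ndarray:
    """Fraction of each mode's (mass-weighted) squared amplitude on given atoms."""
    sel = np.zeros(3 * n_atoms, dtype=bool)
    for i in atom_indices:
        sel[3 * i: 3 * i + 3] = True
    return np.sum(result.modes[:, sel] ** 2, axis=1) / np.sum(result.modes**2, axis=1)
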