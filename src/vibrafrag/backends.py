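"""Energy backends: the pluggable energy/gradient contract, a built-in toy
force field, a quasi-Newton geometry optimizer, and finite-difference Hessians.

The electronic-structure engine is deliberately abstracted behind
:class:`EnergyBackend` (energy in Hartree, gradient in Hartree/Å); any object
with ``energy(geometry)``, ``gradient(geometry)`` and ``name`` plugs in. The
packaged :class:`ToyForceField` — harmonic bonds and angles, optional
Lennard-Jones/Coulomb/12-10 nonbonded terms with 1-2/1-3 exclusions — is the
testing backend: its parameters are generated from a reference geometry so
that the reference is an exact analytic minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .crystal_io import FiniteGeometry
from .errors import ConvergenceError, InvalidArgumentError, MissingParameterError
from .molgraph import UNSATURATED_THRESHOLDS

# Hand-tuned stretching force constants (Hartree/Å²) giving wavenumbers in the
# right spectral neighborhoods (X–H stretches 3-4k cm⁻¹, skeleton ~1k cm⁻¹).
BOND_K_TABLE: dict[frozenset, float] = {
    frozenset(["H", "F"]): 1.00,   # ~3950 cm⁻¹
    frozenset(["O", "H"]): 0.85,   # ~3650 cm⁻¹
    frozenset(["N", "H"]): 0.75,   # ~3400 cm⁻¹
    frozenset(["C", "H"]): 0.60,   # ~3000 cm⁻¹
    frozenset(["C"]): 0.45,        # ~1000 cm⁻¹ single C–C
    frozenset(["C", "O"]): 0.55,   # C=O lands near 1650 via the unsaturated scale
    frozenset(["C", "N"]): 0.50,
    frozenset(["C", "S"]): 0.35,
    frozenset(["O"]): 0.50,
    frozenset(["N"]): 0.50,
}
DEFAULT_BOND_K = 0.50
UNSATURATED_K_SCALE = 2.2      # short (double-bond-like) bonds are stiffer
DEFAULT_ANGLE_K = 0.15         # Hartree/rad²
HBOND_RESTRAINT_K = 0.03       # Hartree/Å², weak intermolecular spring
HBOND_ANGLE_K = 0.015          # Hartree/rad²
HBOND_FLANK_ANGLE_K = 0.0075   # Hartree/rad²
HBOND_TETHER_K = 0.005         # Hartree/Å², breaks the flat contact-axis torsion


@runtime_checkable
class EnergyBackend(Protocol):
    name: str

    def energy(self, g: FiniteGeometry) -> float: ...

    def gradient(self, g: FiniteGeometry) -> np.ndarray: ...


@dataclass
class BondTerm:
    i: int
    j: int
    k: float       # Hartree/Å²
    r0: float      # Å


@dataclass
class AngleTerm:
    i: int
    j: int         # vertex
    k_: int
    k_theta: float  # Hartree/rad²
    theta0: float   # rad


@dataclass
class ToyForceFieldParams:
    """Explicit per-index term lists plus per-element nonbonded parameters.

    ``restraint_*`` terms model hydrogen bonds as weak springs so that
    clusters are bound and have no floppy zero modes beyond rigid-body ones;
    they are kept separate from covalent terms so model builders can strip
    them when emulating an isolated (gas-phase) molecule.
    """

    bond_terms: list[BondTerm] = field(default_factory=list)
    angle_terms: list[AngleTerm] = field(default_factory=list)
    restraint_bond_terms: list[BondTerm] = field(default_factory=list)
    restraint_angle_terms: list[AngleTerm] = field(default_factory=list)
    lj: dict[str, tuple[float, float]] = field(default_factory=dict)  # el -> (eps, sigma)
    charges: np.ndarray | None = None                                 # e, per atom
    hbond_1210_terms: list[BondTerm] = field(default_factory=list)    # k -> eps, r0 -> r0

    def all_bondlike(self) -> list[BondTerm]:
        return self.bond_terms + self.restraint_bond_terms

    def all_angles(self) -> list[AngleTerm]:
        return self.angle_terms + self.restraint_angle_terms


def _angle_and_grads(u: np.ndarray, v: np.ndarray):
    """Angle at the shared vertex and dθ/d(end points); vertex grad by symmetry."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cos = float(np.clip(uh @ vh, -1.0, 1.0))
    theta = float(np.arccos(cos))
    sin = float(np.sqrt(max(1.0 - cos * cos, 0.0)))
    if sin < 1e-8:
        return theta, np.zeros(3), np.zeros(3)
    gi = (cos * uh - vh) / (nu * sin)
    gk = (cos * vh - uh) / (nv * sin)
    return theta, gi, gk


def toy_ff_energy_gradient(
    g: FiniteGeometry, p: ToyForceFieldParams, topology=None
) -> tuple[float, np.ndarray]:
    """Energy (Hartree) and analytic gradient (Hartree/Å) of the toy FF.

    When a bond topology is supplied, every topological bond must have a
    matching bond term (:class:`MissingParameterError` otherwise). Atom pairs
    closer than 0.1 Å abort with an error.
    """
    coords = g.coords
    n = g.n_atoms
    if topology is not None:
        covered = {(min(t.i, t.j), max(t.i, t.j)) for t in p.bond_terms}
        edges = topology.edges if hasattr(topology, "edges") else topology
        for (a, b) in edges:
            if (min(a, b), max(a, b)) not in covered:
                raise MissingParameterError(f"no bond term for bonded pair ({a}, {b})")
    if n > 1:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if np.min(d) < 0.1:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise InvalidArgumentError(f"atoms {i} and {j} overlap (r = {d[i, j]:.3f} Å)")

    energy = 0.0
    grad = np.zeros_like(coords)

    for t in p.all_bondlike():
        rij = coords[t.j] - coords[t.i]
        r = np.linalg.norm(rij)
        dr = r - t.r0
        energy += t.k * dr * dr
        f = 2.0 * t.k * dr * rij / r
        grad[t.i] -= f
        grad[t.j] += f

    for t in p.all_angles():
        u = coords[t.i] - coords[t.j]
        v = coords[t.k_] - coords[t.j]
        theta, gi, gk = _angle_and_grads(u, v)
        dth = theta - t.theta0
        energy += t.k_theta * dth * dth
        pref = 2.0 * t.k_theta * dth
        grad[t.i] += pref * gi
        grad[t.k_] += pref * gk
        grad[t.j] -= pref * (gi + gk)

    for t in p.hbond_1210_terms:
        rij = coords[t.j] - coords[t.i]
        r = np.linalg.norm(rij)
        s = t.r0 / r
        energy += t.k * (5.0 * s**12 - 6.0 * s**10)
        dEdr = t.k * (-60.0 * s**12 + 60.0 * s**10) / r
        f = dEdr * rij / r
        grad[t.i] -= f
        grad[t.j] += f

    if p.lj or p.charges is not None:
        from .elements import COULOMB_HARTREE_ANGSTROM

        excluded = set()
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for t in p.all_bondlike():
            adj[t.i].add(t.j)
            adj[t.j].add(t.i)
            excluded.add((min(t.i, t.j), max(t.i, t.j)))
        for i in range(n):
            for a in adj[i]:
                for b in adj[a]:
                    if b != i:
                        excluded.add((min(i, b), max(i, b)))
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excluded:
                    continue
                rij = coords[j] - coords[i]
                r = float(np.linalg.norm(rij))
                dEdr = 0.0
                if p.lj and g.elements[i] in p.lj and g.elements[j] in p.lj:
                    ei, si = p.lj[g.elements[i]]
                    ej, sj = p.lj[g.elements[j]]
                    eps = np.sqrt(ei * ej)
                    sig = 0.5 * (si + sj)
                    sr6 = (sig / r) ** 6
                    energy += 4.0 * eps * (sr6 * sr6 - sr6)
                    dEdr += 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                if p.charges is not None:
                    qq = p.charges[i] * p.charges[j] * COULOMB_HARTREE_ANGSTROM
                    energy += qq / r
                    dEdr += -qq / (r * r)
                f = dEdr * rij / r
                grad[i] -= f
                grad[j] += f

    return float(energy), grad


class ToyForceField:
    """EnergyBackend adapter around :func:`toy_ff_energy_gradient`."""

    def __init__(self, params: ToyForceFieldParams, topology=None, name: str = "toyff"):
        self.params = params
        self.topology = topology
        self.name = name

    def energy(self, g: FiniteGeometry) -> float:
        return toy_ff_energy_gradient(g, self.params, self.topology)[0]

    def gradient(self, g: FiniteGeometry) -> np.ndarray:
        return toy_ff_energy_gradient(g, self.params, self.topology)[1]


# ---------------------------------------------------------------------------
# Parameter generation
# ---------------------------------------------------------------------------

def bond_force_constant(el_i: str, el_j: str, length: float) -> float:
    k = BOND_K_TABLE.get(frozenset([el_i, el_j]), DEFAULT_BOND_K)
    thr = UNSATURATED_THRESHOLDS.get(frozenset([el_i, el_j]))
    if thr is not None and length < thr:
        k *= UNSATURATED_K_SCALE
    return k


def parameterize(geometry: FiniteGeometry, bonds, hbond_contacts=()) -> ToyForceFieldParams:
    """Build toy-FF parameters whose exact minimum is the given geometry.

    Covalent bonds and all angles at each vertex get harmonic terms with
    r0/θ0 read off the reference; each H-bond contact (d, h, a) adds a weak
    H···A spring plus D–H···A and H···A–X flanking angle restraints so the
    cluster has no floppy internal modes.
    """
    p = ToyForceFieldParams()
    coords = geometry.coords
    adj: dict[int, list[int]] = {i: [] for i in range(geometry.n_atoms)}
    for (a, b) in bonds:
        adj[a].append(b)
        adj[b].append(a)
        r0 = float(np.linalg.norm(coords[a] - coords[b]))
        k = bond_force_constant(geometry.elements[a], geometry.elements[b], r0)
        p.bond_terms.append(BondTerm(a, b, k, r0))
    for j in range(geometry.n_atoms):
        nbs = sorted(adj[j])
        for x in range(len(nbs)):
            for y in range(x + 1, len(nbs)):
                i, k_ = nbs[x], nbs[y]
                theta, _, _ = _angle_and_grads(coords[i] - coords[j], coords[k_] - coords[j])
                p.angle_terms.append(AngleTerm(i, j, k_, DEFAULT_ANGLE_K, theta))
    for (d, h, a) in hbond_contacts:
        r0 = float(np.linalg.norm(coords[h] - coords[a]))
        p.restraint_bond_terms.append(BondTerm(h, a, HBOND_RESTRAINT_K, r0))
        theta, _, _ = _angle_and_grads(coords[d] - coords[h], coords[a] - coords[h])
        p.restraint_angle_terms.append(AngleTerm(d, h, a, HBOND_ANGLE_K, theta))
        for nb in adj[a]:
            theta, _, _ = _angle_and_grads(coords[h] - coords[a], coords[nb] - coords[a])
            p.restraint_angle_terms.append(
                AngleTerm(h, a, nb, HBOND_FLANK_ANGLE_K, theta))
        # a cross-junction tether between off-axis flank atoms: rotation about
        # the D-H···A axis leaves every bond/angle term unchanged (a flat
        # torsion), so one weak spring across the contact makes it bound
        nd = min((x for x in adj[d] if x != h), default=d)
        na = min((x for x in adj[a] if x != h), default=a)
        if nd != na:
            r0 = float(np.linalg.norm(coords[nd] - coords[na]))
            p.restraint_bond_terms.append(BondTerm(nd, na, HBOND_TETHER_K, r0))
    return p


def restrict_params(p: ToyForceFieldParams, index_map: dict[int, int]) -> ToyForceFieldParams:
    """Keep only terms whose atoms all survive, remapped through index_map."""
    out = ToyForceFieldParams(lj=dict(p.lj))

    def keep_bond(t: BondTerm):
        return t.i in index_map and t.j in index_map

    def keep_angle(t: AngleTerm):
        return t.i in index_map and t.j in index_map and t.k_ in index_map

    out.bond_terms = [BondTerm(index_map[t.i], index_map[t.j], t.k, t.r0)
                      for t in p.bond_terms if keep_bond(t)]
    out.restraint_bond_terms = [BondTerm(index_map[t.i], index_map[t.j], t.k, t.r0)
                                for t in p.restraint_bond_terms if keep_bond(t)]
    out.hbond_1210_terms = [BondTerm(index_map[t.i], index_map[t.j], t.k, t.r0)
                            for t in p.hbond_1210_terms if keep_bond(t)]
    out.angle_terms = [AngleTerm(index_map[t.i], index_map[t.j], index_map[t.k_],
                                 t.k_theta, t.theta0)
                       for t in p.angle_terms if keep_angle(t)]
    out.restraint_angle_terms = [AngleTerm(index_map[t.i], index_map[t.j],
                                           index_map[t.k_], t.k_theta, t.theta0)
                                 for t in p.restraint_angle_terms if keep_angle(t)]
    if p.charges is not None:
        old = sorted(index_map, key=index_map.get)
        out.charges = np.asarray(p.charges)[old]
    return out


def shift_donor_h_r0(p: ToyForceFieldParams, donor_h_pairs, delta: float) -> ToyForceFieldParams:
    """Shorten selected D–H reference lengths by ``delta`` Å (gas-phase emulation).

    H-bonding elongates the donor X–H bond; a model stripped of its H-bond
    environment should relax toward the shorter gas-phase length.
    """
    pairs = {(min(a, b), max(a, b)) for (a, b) in donor_h_pairs}
    out = ToyForceFieldParams(
        angle_terms=list(p.angle_terms), lj=dict(p.lj),
        charges=None if p.charges is None else np.asarray(p.charges).copy(),
    )
    for t in p.bond_terms:
        key = (min(t.i, t.j), max(t.i, t.j))
        r0 = t.r0 - delta if key in pairs else t.r0
        out.bond_terms.append(BondTerm(t.i, t.j, t.k, r0))
    out.restraint_bond_terms = list(p.restraint_bond_terms)
    out.restraint_angle_terms = list(p.restraint_angle_terms)
    out.hbond_1210_terms = list(p.hbond_1210_terms)
    return out


# ---------------------------------------------------------------------------
# Geometry optimization
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceCriteria:
    """All three thresholds must hold simultaneously on one accepted step."""

    max_energy_change: float = 1e-5    # Hartree
    max_force: float = 0.002           # Hartree/Å, max |gradient component|
    max_displacement: float = 0.005    # Å, max per-atom step length
    max_steps: int = 500

    def __post_init__(self):
        if min(self.max_energy_change, self.max_force, self.max_displacement) <= 0:
            raise InvalidArgumentError("convergence thresholds must be positive")
        if self.max_steps < 1:
            raise InvalidArgumentError("max_steps must be >= 1")


@dataclass
class OptimizationResult:
    model: object                      # ClusterModel or FiniteGeometry, matching input
    steps: int
    energy: float
    max_force: float
    energy_change: float
    max_displacement: float
    converged: bool = True


_MAX_ATOM_STEP = 0.25  # Å trust radius per BFGS step


def optimize_geometry(c, b: EnergyBackend,
                      crit: ConvergenceCriteria | None = None) -> OptimizationResult:
    """BFGS with backtracking line search; energy never increases between steps.

    Accepts a ClusterModel (roles preserved) or a bare FiniteGeometry.
    Convergence requires |ΔE|, max gradient component and max atom
    displacement to satisfy the criteria simultaneously on one step; running
    out of steps raises :class:`ConvergenceError` carrying the last geometry.
    """
    crit = crit or ConvergenceCriteria()
    is_cluster = hasattr(c, "geometry")
    geom = c.geometry.copy() if is_cluster else c.copy()
    n3 = geom.n_atoms * 3
    x = geom.coords.reshape(-1).copy()

    def eval_at(vec):
        geom.coords = vec.reshape(-1, 3)
        e = b.energy(geom)
        g = b.gradient(geom).reshape(-1)
        return e, g

    e, g = eval_at(x)
    hinv = np.eye(n3)
    last = OptimizationResult(None, 0, e, float(np.max(np.abs(g))), np.inf, np.inf,
                              converged=False)
    for step in range(1, crit.max_steps + 1):
        p = -hinv @ g
        max_atom = np.max(np.linalg.norm(p.reshape(-1, 3), axis=1)) if n3 else 0.0
        if max_atom > _MAX_ATOM_STEP:
            p *= _MAX_ATOM_STEP / max_atom
        slope = g @ p
        if slope > 0:   # reset a corrupted curvature estimate
            hinv = np.eye(n3)
            p = -g
            slope = g @ p
        alpha = 1.0
        for _ in range(40):
            e_new, g_new = eval_at(x + alpha * p)
            if e_new <= e + 1e-4 * alpha * slope:
                break
            alpha *= 0.5
        else:
            alpha = 0.0
            e_new, g_new = e, g
        s = alpha * p
        y = g_new - g
        de = e_new - e
        disp = float(np.max(np.linalg.norm(s.reshape(-1, 3), axis=1)))
        x = x + s
        if s @ y > 1e-12:
            rho = 1.0 / (s @ y)
            eye = np.eye(n3)
            hinv = ((eye - rho * np.outer(s, y)) @ hinv @ (eye - rho * np.outer(y, s))
                    + rho * np.outer(s, s))
        e, g = e_new, g_new
        fmax = float(np.max(np.abs(g)))
        last = OptimizationResult(None, step, e, fmax, abs(de), disp, converged=False)
        if (abs(de) <= crit.max_energy_change and fmax <= crit.max_force
                and disp <= crit.max_displacement):
            geom.coords = x.reshape(-1, 3)
            out = c.with_coords(geom.coords) if is_cluster else geom
            return OptimizationResult(out, step, e, fmax, abs(de), disp, converged=True)

    geom.coords = x.reshape(-1, 3)
    out = c.with_coords(geom.coords) if is_cluster else geom
    last.model = out
    raise ConvergenceError(
        f"geometry optimization did not converge in {crit.max_steps} steps "
        f"(max |F| = {last.max_force:.2e} Hartree/Å)", last_model=out, report=last)


# ---------------------------------------------------------------------------
# Hessians
# ---------------------------------------------------------------------------

def finite_difference_hessian(b: EnergyBackend, g: FiniteGeometry,
                              step: float = 0.005) -> np.ndarray:
    """Central differences of the gradient, symmetrized to (H + Hᵀ)/2."""
    if step <= 0:
        raise InvalidArgumentError("finite-difference step must be positive")
    n3 = g.n_atoms * 3
    h = np.empty((n3, n3))
    work = g.copy()
    flat = g.coords.reshape(-1)
    for col in range(n3):
        x = flat.copy()
        x[col] += step
        work.coords = x.reshape(-1, 3)
        gp = b.gradient(work).reshape(-1)
        x[col] -= 2 * step
        work.coords = x.reshape(-1, 3)
        gm = b.gradient(work).reshape(-1)
        h[:, col] = (gp - gm) / (2.0 * step)
    return 0.5 * (h + h.T)


def analytic_harmonic_hessian(g: FiniteGeometry, p: ToyForceFieldParams,
                              step: float = 1e-4) -> np.ndarray:
    """Reference Hessian of the toy FF via tight finite differences.

    For the purely harmonic bond/angle form at its minimum this agrees with
    the exact second derivative to numerical precision; used as the
    cross-check path against :func:`finite_difference_hessian` at coarse step.
    """
    return finite_difference_hessian(ToyForceField(p), g, step=step)
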