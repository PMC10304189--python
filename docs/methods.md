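# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `vibrafrag`, in the order the pipeline uses them.

## Crystal input and bond perception

CIF reading supports P1 blocks and blocks with an explicit symmetry-operator
loop (`_symmetry_equiv_pos_as_xyz` or the `_space_group_symop` spelling);
named space-group lookup is deliberately unsupported, so inputs must carry
their operators. After expansion, sites closer than 0.3 Å (minimum-image
Cartesian) are merged — standard crystallographic duplicate tolerance.
Partially occupied sites are rejected: cluster construction is undefined for
disorder. Fractional coordinates exist only inside `CrystalStructure`;
everything downstream is Cartesian Å.

Covalent bonds are perceived geometrically: sites are bonded iff their
minimum-image distance is ≤ r_cov(i) + r_cov(j) + t with Cordero radii and
t = 0.40 Å (user-overridable); H–H bonds are excluded. The 27-neighbor-image
search is exact for any cell whose shortest height exceeds the largest
cutoff, which holds for all intended inputs. Molecules are connected
components, unwrapped by a breadth-first walk accumulating image shifts;
a component that closes on itself at a nonzero net shift is an infinite
polymer and is rejected. The lowest site index anchors each component at
shift (0,0,0), and molecules are ordered by (Hill formula, centroid) — both
choices exist purely for determinism.

## Hydrogen bonds

A contact D–H···A counts when d(H···A) ≤ 2.5 Å, d(D···A) ≤ 3.5 Å and the
angle at H is ≥ 120°, with D ∈ {N, O} and A ∈ {N, O, S} by default (S as
acceptor because thioethers occur in the benchmark drugs; F is added for the
HF toy fixture). These are conventional crystallographic windows; all are
parameters of `HBondCriteria`. Every passing triplet is reported —
bifurcated H-bonds are not pruned, so the molecule-level adjacency carries
an edge weight equal to the number of contacts. C–H donors are excluded by
default and can be enabled by widening the donor set.

## Cluster models

*Repeating unit.* The central molecule (user index, or by default the one
whose centroid is nearest the supercell centroid — a deterministic stand-in
for an arbitrary choice) plus every molecule sharing ≥ 1 intermolecular
H-bond with it, whole molecules only. The build refuses to proceed when the
central molecule is closer to any supercell face than the donor–acceptor
cutoff, because the H-bond shell could then be truncated by the boundary;
the fix is a larger supercell (supercell size is a user decision — no
heuristic is imposed).

*Fragment interception.* Per-atom retention over the neighbor molecules:
keep an atom iff (i) it is within `radius` (default 4.0 Å) of any
central-molecule atom, or (ii) it belongs to the covalent functional group
of an H-bond to the central molecule — the donor/acceptor heavy atom, its
directly bonded neighbors, and their hydrogens — or (iii) it sits in a
conjugated group already touched by retained atoms. The retained set is
closed under "keep hydrogens riding on retained heavy atoms". Every severed
single covalent bond is replaced by a hydrogen link atom placed along the
cut direction at 1.09/1.01/0.96 Å from C/N/O; cutting a bond inside a
conjugated group is refused (enlarge the radius instead). A whole-molecule
mode (`cap=False`) keeps or drops neighbor molecules intact with no link
atoms. "Conjugated" is operationalized geometrically: an atom participates
in a bond shorter than a single-bond threshold for its element pair
(C–C 1.45, C–N 1.40, C–O 1.30 Å, …), or is O/N bonded to such an atom; this
is a reproducible stand-in for an electronic-structure criterion.

Atom roles (central/neighbor/cap) survive every operation; the central
molecule is never trimmed, and the central model is, by construction, the
coordinate-exact central subset of the optimized repeating unit.

## Energy backend and toy force field

Backends implement `energy` (Hartree) and `gradient` (Hartree/Å) on a finite
geometry; DFT engines attach here. The packaged toy force field is

E = Σ k_b (r − r₀)² + Σ k_θ (θ − θ₀)² + [LJ + Coulomb + 12-10 H-bond terms]

with 1-2/1-3 exclusions for the nonbonded part (which defaults to off).
Parameters are generated from a reference geometry: r₀/θ₀ are read off the
reference, so the reference is an exact analytic minimum; force constants
come from a per-element-pair table tuned to put X–H stretches at 3–4×10³
cm⁻¹ and skeleton modes near 10³ cm⁻¹ (bonds shorter than the unsaturation
threshold get a ×2.2 stiffening so carbonyls land near 1650 cm⁻¹). Each
H-bond contributes a weak H···A spring (0.03 Hartree/Å²), D–H···A and
flanking angle restraints, and one cross-junction tether (0.005 Hartree/Å²)
between off-axis flank atoms — without the tether, rotation about the
D–H···A axis leaves every bond and angle term unchanged and the cluster has
flat torsions. Link-atom caps get a standard X–H bond term and angle terms
at their as-built geometry.

Gas-phase (isolated-molecule) parameter sets drop the H-bond restraints and
shorten donor X–H reference lengths by 0.02 Å, reflecting the real
elongation a hydrogen bond imposes on its donor. This is what makes the
single-molecule model relax away from the in-crystal geometry while the
central model keeps it — the mechanism, not the magnitude, of the
single/central/fragment accuracy ordering.

## Optimization and Hessians

Geometry optimization is BFGS with a backtracking (Armijo) line search, a
0.25 Å per-atom trust radius, and an automatic reset of the inverse-Hessian
estimate if curvature information goes bad. Convergence requires, on one
accepted step simultaneously: |ΔE| ≤ 1×10⁻⁵ Hartree, max gradient component
≤ 0.002 Hartree/Å, and max per-atom displacement ≤ 0.005 Å (defaults of
`ConvergenceCriteria`). Running out of steps raises an error carrying the
last geometry — an unconverged structure is never returned silently. Note
that with the default force tolerance, coordinates along the softest
restraint directions (k ≈ 0.005 Hartree/Å²) may legitimately stop up to
≈ F_max/2k ≈ 0.2 Å from the minimum.

Hessians are central finite differences of the analytic gradient (default
step 0.005 Å, matching the displacement tolerance scale), symmetrized to
(H + Hᵀ)/2. Finite-difference truncation error grows as step², which is why
the acoustic sum rule (translation invariance) is verified at a 5×10⁻⁴ Å
step where it holds below 10⁻⁶ Hartree/Å².

## Vibrational analysis

The Hessian is mass-weighted (H̃ᵢⱼ = Hᵢⱼ/√(mᵢmⱼ)), the 3 translational and
3 rotational directions (2 for collinear geometries, detected via a 10⁻⁶
moment-of-inertia ratio) are built at the center of mass, orthonormalized,
and projected out; after diagonalization the n_projected eigenvalues nearest
zero are removed, keeping their magnitudes for diagnostics. Wavenumbers are
ν̃ = sign(λ)√|λ|/(2πc) with CODATA constants; imaginary modes appear as
negative wavenumbers, and `has_imaginary` uses a 1 cm⁻¹ threshold to ignore
numerical zeros. Scale factors multiply frequencies in full precision; all
*reported* frequencies round half-up to two decimals, the precision of the
packaged benchmark tables.

IR intensities are unit by default; a backend exposing fixed charges can
supply numerical dipole derivatives, but none of the shipped analyses depend
on intensities beyond spectrum rendering.

## Matching and statistics

Peak matching is one-to-one within a window (default 100 cm⁻¹).
`nearest_greedy` walks experimental peaks from high to low wavenumber, each
taking the nearest unused calculated peak. `optimal` solves the rectangular
assignment problem minimizing total |exp − calc| (scipy), with a 10⁻⁶·rank
crossing penalty so that exact ties resolve to the order-preserving,
non-crossing assignment — physically, assignments should not cross; the
penalty is far below any spectroscopic scale. Unmatched peaks on either side
are reported, not scored. MAE/RMSE are plain means over matched pairs
(RMSE ≥ MAE always, by the power-mean inequality); the FG/NFG decomposition
tags a row FG when its mode label involves an X–H (X ∈ N, O, S) or
carbonyl-type motion — a label-text rule, user-overridable per row.

The packaged benchmark tables are vendored exactly as printed. Two printed
values are *not* consistent with the stated 0.99 factor: the LAM 1041.08 →
1033.67 row (0.99 gives 1030.67) and the entire REP scaled column (which
matches a factor ≈ 0.9795). The package follows the stated 0.99 and treats
those rows as non-reproducible print artifacts; the headline MAE/RMSE of
the original benchmark ("for all data") cover appendix rows that are not
packaged, so only printed-subset statistics are computed here.

## Pipeline and pseudo-experiment

`run_pipeline` executes: single build → gas-phase optimize → frequencies;
repeating-unit build → crystal-FF optimize; central extraction →
frequencies at the in-cluster geometry; fragment interception →
frequencies with the H-bond terms retained; scaling; matching; per-model
MAE/RMSE. Absent a measured peak list, pseudo-experimental peaks are taken
from the optimized repeating unit's modes with ≥ 50% mass-weighted squared
amplitude on central atoms (the same locality filter, also user-selectable,
restricts which fragment modes are reported). Frequencies below 10 cm⁻¹ are
dropped as numerical zeros. The whole report — config, hash, frequencies,
summaries — is deterministic for a fixed input; the output directory is
excluded from the provenance hash.

## What the toy fixtures do and do not show

The generator builds four periodic toy crystals (HF chain, water chains,
formamide chains, an ethanol-like H-bonded dimer) at idealized geometry:
every bond/angle at its reference value, H-bond separations 1.75–1.8 Å
inside all default detection windows, donor X–H elongated by 0.02 Å, planar
centers slightly pyramidalized (exactly planar centers have harmonically
flat out-of-plane directions under a bond+angle force field). Each fixture
carries its ground truth — bonds, H-bonds, molecule count, and a force field
whose exact minimum is the noise-free geometry. "water_sheet" is parallel
O–H···O chains stacked without inter-row contacts, not a 2-D net.

Passing the pipeline on these fixtures demonstrates the *machinery*: exact
perception, role bookkeeping, convergence behavior, and the qualitative
single < central < fragment accuracy ordering that follows mechanically from
which interaction terms each model retains. It does not validate DFT-level
accuracy on real crystals: the toy force field has no electrostatics or
dispersion by default, its cluster terms are built at the reference geometry
(so the central model's configuration advantage is mild), and the published
drug benchmarks require the original crystal structures and a DFT engine.
Simulation sizes throughout (5-molecule chains, ≤ 36-atom clusters) were
chosen as the smallest systems exhibiting a complete interior H-bond shell.

## Known limitations

- No named space-group database; no disorder/partial occupancy; neutral
  molecules only.
- No anharmonic corrections; harmonic frequencies plus an empirical scale
  factor are the ceiling of this workflow by design.
- The conjugation flag is geometric, not electronic; unusual bond lengths
  can mis-tag groups.
- Periodic (phonon) calculations are out of scope: all models are finite
  clusters in vacuum.
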