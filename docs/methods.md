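# Methods

This note documents the models, parameter choices and known limitations of
`metallobuild`. Everything stated here is computed by the test suite or the
acceptance script; nothing is quoted from external measurements.

## Scope and assumptions

The builder targets *mononuclear* complexes specified as 2D molecular
graphs: one metal, plus ligands given as SMILES with explicit
coordinating-atom (CA) indices (0-based, into the heavy-atom order of the
SMILES; the indexing survives hydrogen addition because hydrogens are
appended after the heavy atoms). Haptic (η-bonded) ligands, ligand types
requiring metal-adjacent secondary atoms, polynuclear complexes, tautomer
enumeration and solvent models are out of scope. Coordination numbers 1–12
are supported.

## Element data and electronic-state defaults

`data/elements.csv` ships one row per element: single-bond covalent radius,
van der Waals radius, and — for metals — ordered lists of common oxidation
states (most common first) and coordination numbers. Radii follow the
standard literature compilations (Cordero-type covalent radii,
Alvarez/Bondi-type vdW radii). The per-metal oxidation-state and CN
defaults are **reconstructions** from general coordination-chemistry
references, not a verbatim copy of any single published table; users with
better priors for their chemistry should override per request.

Spin multiplicities are *derived*, not tabulated: the metal ion's d- or
f-electron count at the assigned oxidation state is filled high-spin
(Hund), giving `multiplicity = unpaired + 1`. Because every closed-shell
ligand contributes an even electron count, total-electron parity is fixed
by `Z(metal) − oxidation`, and the Hund value is parity-consistent by
construction; user-supplied multiplicities are validated against that
parity. Limitations: no ligand-field (low-spin) corrections — Au(III) or
strong-field d⁶ complexes default to their high-spin counts — and no
Jahn–Teller-aware geometry defaults.

Actinides (Z 89–103) map to their same-group lanthanide (Ac→La … Lr→Lu)
only when the active calculator does not support them; the proxy keeps the
requested charge and multiplicity, which preserves the f-electron count.
The built-in scaffold calculator supports the full table, so the swap
engages only for user-supplied backends with a restricted element range.

## Coordination cores and ligand types

`data/core_geometries.json` stores 27 idealized polyhedra (CN 1–12) as unit
vectors; the roster is the standard textbook set (octahedral + trigonal
prismatic at CN 6, three CN 7 shapes, four CN 8 shapes including the D2d
dodecahedron, tricapped trigonal prism and capped square antiprism at CN 9,
up to icosahedral/cuboctahedral at CN 12). Antiprism heights are solved for
equal edge lengths; the D2d dodecahedron uses the idealized
Hoard–Silverton polar angles (36.85° / 69.46°). The set is a reconstruction
of the usual idealized shapes and is user-extensible at run time
(`register_core_geometry`).

`data/ligand_types.json` defines coordination types by their CA–M–CA angle
patterns (monodentate; bidentate cis 90° / trans 180°; tridentate fac
(3×90°) / mer (90°, 90°, 180°); tetradentate planar / tripodal;
pentadentate planar; hexadentate octahedral). Classification minimizes the
summed absolute angular deviation under an optimal bipartite pairing of
angle lists (`linear_sum_assignment`), which keeps fac/mer discrimination
robust; ties break by table order, and with no estimates the first (most
common) type of the denticity is returned. In the build pipeline the
estimates come from the prepared ligand geometry via the law of cosines on
the CA–CA separation and the covalent-radius M–CA lengths.

## Binding-site mapping and pseudo-energy

A ligand of denticity *d* may bind any combination of *d* core sites whose
pairwise-angle multiset matches its type template within an angle tolerance
(default 15°, wide enough for distorted bites, narrow enough to keep
cis/trans distinct on the octahedron); the match uses the optimal pairing,
and the summed deviation is retained for tie-breaking. Conflict-free
assignments for all ligands are enumerated by depth-first search; the cap
on enumerated assignments (default 10⁶) applies to the conflict-pruned
yield, beyond which a deterministic pseudo-energy-pruned beam (width 10⁴)
takes over, trading completeness for bounded work.

The pseudo-energy of an assignment is `Σ_{i<j} b_i b_j / d_ij` over all
occupied sites (unit heuristic charges by default, per-ligand overridable;
`d_ij` the chord between unit site vectors). It is invariant under global
rotation and prefers spread-out (trans over cis) placements. The functional
form is this package's own reconstruction of a "charge-spreading"
heuristic; its counting behavior (n! raw maps for n distinct monodentates,
C(n, k) unique maps after identical-ligand deduplication) and its full-sort
ranking are pinned by tests. Deduplication canonicalizes each assignment by
grouping site tuples per ligand-identity label; quotienting additionally by
the core's proper rotation group is available but **off by default**, since
the counting identities above are defined at the ligand-identity level.

## Ligand 3D generation

Initial geometries come from RDKit (ETKDG embedding with a fixed seed +
MMFF94, UFF fallback). Distance bounds are then built from that geometry:

| pair class | lower | upper |
|---|---|---|
| bonded | d₀ − 0.03 Å | d₀ + 0.03 Å |
| geminal (1-3) | d₀ − 0.10 Å | d₀ + 0.10 Å |
| ≥ 1-4 | 0.85 × (vdw_i + vdw_j) | 100 Å |

For pairs sharing a ring the vdW floor is capped at 0.9 × d₀: ring
through-space separations (benzene para C···C = 2.78 Å) legitimately
undercut vdW sums and an uncapped floor would be infeasible. Bounds are
triangle-smoothed (shortest-path tightening of uppers, inverse-triangle
raising of lowers).

Embedding samples a distance matrix uniformly inside the bounds, builds the
Gram matrix by double centering, takes the top-3 eigenvector coordinates,
and polishes with L-BFGS on the squared bounds violations. A conformer is
accepted when its worst violation is ≤ ε_dg = 0.35 Å; otherwise up to 5
retries with incremented seeds, then an error carrying the worst pair. The
procedure is bitwise deterministic per seed.

Cleaning is a two-stage force-field pass (MMFF94 where parametrized, UFF
otherwise): first with CAs positionally fixed, then free. A cleaned
conformer must keep every bond within 20% of its **prepared reference
length** — the reference is the FF-relaxed geometry rather than
covalent-radius sums, because radius sums misclassify multiple bonds (a
C≡N at 1.16 Å deviates 21% from the 1.47 Å single-bond sum while being
perfectly healthy).

Monodentate placement is rigid: a deterministic pre-position (CAs
superposed on the bond-length-scaled site vectors, body oriented away from
the metal) followed by a rotation-only Kabsch about the origin, whose
residual is the rotRMSD. Multidentate ligands are instead embedded
*against their site*: the metal and the site targets enter the bounds
matrix (metal–CA pinned to the covalent-radius-sum length ± 0.02 Å, CA–CA
pinned to the site chords ± 0.05 Å, metal–other floored at 0.8 × covalent
sums), so the generated conformer already spans the site; a metal-free
MMFF polish with CAs pinned then absorbs residual strain, guarded by a
metal-clearance check (0.7 × covalent sums) that falls back to the
unpolished embedding. A site whose chords the ligand backbone cannot span
surfaces as an infeasible-bounds error and that candidate is dropped.
Note the rotRMSD used in assembly is rotation-only about the metal; the
kmRMSD metric below superposes freely with translation — the two are
deliberately distinct.

## Assembly, calculator, relaxation

Ligands are assembled greedily from highest to lowest denticity (ties:
more heavy atoms first, then input order). Candidates failing the
pre-placement distance checks are discarded; survivors are scored by
`energy × (1 / max(rotRMSD, 0.01 Å))` and the minimum wins. The 0.01 Å
floor protects exactly-aligned monodentates from division by zero. The
bias presumes total energies are negative (as for electronic-structure
totals); the scaffold potential therefore includes a per-atom reference
energy of −100 kcal/mol, an additive constant within a fixed stoichiometry
that fixes the sign convention without affecting conformer ranking.

The calculator is pluggable (`evaluate` / `relax` / `supports`). The
built-in **scaffold potential** (kcal/mol, Å):

* harmonic bonds, k = 300, r₀ = (rcov_i + rcov_j) scaled by bond order
  (1.0 / 0.93 aromatic / 0.87 double / 0.78 triple);
* Kepert repulsion `50 / d` between atoms geminal *through a metal* —
  coordinated atoms repel on the coordination sphere, so six monodentates
  relax to the octahedron from any CN 6 start (the trigonal-prism start
  collapses onto the octahedral solution and is removed as a duplicate);
* Lennard-Jones (ε = 0.05, r_min = 0.8 × vdW sum) plus Coulomb on formal
  charges for pairs ≥ 3 bonds apart;
* during relaxation only, harmonic geminal restraints (k = 60) snapshotted
  from the input geometry on pairs geminal through an *organic* center,
  preserving intra-ligand angles. The restraints are zero at the input, so
  the relax objective equals the single-point energy there and the L-BFGS
  minimizer makes the reported energy non-increasing by construction (if a
  line search ever ends higher, the input is returned unchanged and
  flagged unconverged).

Relaxation runs scipy's L-BFGS-B with analytic gradients (default 300
iterations).

## Sanity checks

Pre-evaluation (three distance-cutoff checks): (1) inter-ligand contacts
≥ 0.6 × (vdw_i + vdw_j); (2) non-bonded intra-complex contacts ≥ 0.65 ×
(rcov_i + rcov_j); (3) every CA within ± 0.45 Å of its target M–CA length.
Post-relaxation adds graph fidelity: every bond inside
[0.7, 1.3] × (rcov_i + rcov_j), and no *heavy* atom at graph distance ≥ 3
from the metal closer to it than the nearest bonded CA. Hydrogens and 1-/2-
bond neighbors are exempt from the last rule: chelate backbone C–H and CA
substituent hydrogens necessarily sit 2.3–2.6 Å from a large lanthanide
(nearest CA ≈ 2.7 Å) without any bonding interaction, and the all-atom
version of the rule rejects every chemically sane chelate. All constants
are package choices pinned in `SanityParams` and exercised by tests.

## Pipeline defaults and determinism

Per build: up to 20 core symmetries per CN (the shipped library has ≤ 4);
the 10 lowest-pseudo-energy assignments per core; 3 distance-geometry
conformers per ligand; the 10 lowest-energy assembled complexes relaxed;
duplicates removed at 0.5 Å full kmRMSD; output ranked ascending in
energy. A master seed fans out deterministically (affine congruential
derivation, kept below 2³¹) to per-ligand, per-conformer embedding seeds;
identical (request, seed) pairs give bitwise-identical coordinates and
energies. Attrition accounting (assembled = survivors + per-stage
rejections) is asserted on every build.

## Structure comparison

`km_rmsd` alternates optimal same-element assignment (Hungarian algorithm
on squared distances) with rigid Kabsch superposition (translation
included) until the RMSD change is < 1e-8 or 50 iterations, starting from
the identity, 8 fixed-seed random rotations, and up to 40 deterministic
*anchor-pair* rotations (two well-separated reference atoms of one
structure aligned against every same-element candidate pair of the other).
The anchor starts are what make the metric exact on congruent
permuted/rotated copies of highly symmetric structures, where random
restarts alone stall in local minima; the metric is symmetrized by
evaluating both directions. It is a pseudo-metric: non-negative, symmetric
and zero on congruent copies, but the triangle inequality is not guaranteed
by the alternating optimization. Hydrogens are included by default (a flag
excludes them). `c_km_rmsd` applies the same metric to the subgraph within
two bond hops of the metal (build provenance graph when available,
otherwise a 1.25 × covalent-sum distance criterion), which compares
coordination geometry without letting floppy ligand tails dominate.
Duplicate removal scans conformers in ascending energy and drops any within
0.5 Å full kmRMSD of a retained one, so each cluster keeps its
lowest-energy member.

## Synthetic fixtures: what they do and do not show

The fixture registry (hexaaqua Fe, mixed-denticity Ce, CN 8 mono-dentate
sets, CN 9 aqua La) exercises every pipeline stage with ligands small
enough (≤ 12 heavy atoms) that exhaustive oracles — full permutation RMSD,
complete assignment enumeration, rotation-grid alignment — remain feasible,
and each builds end to end in well under a minute on one CPU. They emulate
the combinatorial and geometric structure of real builds (high CN,
identical-ligand symmetry, chelate strain) but not the conformational
complexity of large flexible ligands, crystal-packing effects, or the
energetics of a quantum-chemical evaluator; a passing suite demonstrates
the correctness of the machinery, not the thermochemical accuracy of the
scaffold potential. The hexaaqua reference structure is constructed
analytically (O on exact octahedral sites at covalent-radius-sum distances,
water planes containing the radial axis) and is used as the ground truth
for metric and sanity-check tests.

## Known limitations

* The scaffold potential is a structural cleanup tool, not a
  thermochemical model; energy *rankings* between substantially different
  ligand sets are not meaningful. Swap in a quantum or tight-binding
  calculator via the contract for real energetics.
* Ligand-type coverage stops at the shipped angle table; exotic
  coordination modes need user-added types.
* Chelates whose natural bite angle is far from any idealized site pattern
  (common for the largest metals) are built under strain; the site
  tolerance and post-relaxation checks decide survival, and some such
  builds legitimately return fewer conformers.
* Assignment deduplication is positional; Δ/Λ stereoisomer labeling is not
  performed.
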