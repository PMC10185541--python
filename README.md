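# metallobuild

3D conformer construction for mononuclear metal–organic complexes from 2D
inputs.

Computational studies of coordination chemistry — lanthanide/actinide
separations, homogeneous catalysis, force-field and tight-binding training
sets — need reasonable 3D starting structures for arbitrary metal–ligand
combinations, including high coordination numbers (CN 8–12) where hand
building and organic-molecule conformer tools both fail. `metallobuild`
takes a purely graph-level description of a complex:

* a metal element symbol (optionally oxidation state, spin multiplicity and
  coordination number — sensible defaults are assigned from element tables
  and high-spin electron counting),
* each ligand as a SMILES string plus the 0-based indices of its
  coordinating atoms (CAs),

and returns ranked, deduplicated, chemistry-checked 3D conformers.

## Method

1. **Coordination cores.** For the requested CN, idealized coordination
   polyhedra (octahedral, square antiprismatic, tricapped trigonal
   prismatic, …; CN 1–12) are taken from an extensible data table. Each
   core is a set of unit vectors around the metal.
2. **Binding-site mapping.** Each ligand is classified by its CA–M–CA angle
   pattern (bidentate cis/trans, tridentate fac/mer, …) and matched against
   every combination of core sites whose inter-site angles fit within a
   tolerance. Conflict-free mappings of all ligands (no shared sites) are
   enumerated, reduced by identical-ligand permutation symmetry, and ranked
   by a Coulomb-like pseudo-energy
   `E = Σ_{i<j} b_i b_j / d_ij` (heuristic charge `b = 1` on every occupied
   site, `d_ij` the chord distance), which favors evenly spread ligands —
   e.g. a CN 8 complex with 8 distinct monodentate ligands has
   8! = 40,320 raw mappings, while 4 water + 4 ethanol collapse to
   8C4 = 70 unique ones.
3. **Ligand 3D generation.** Ligands are initialized from SMILES and
   force-field relaxed (MMFF94/UFF via RDKit), then re-embedded by distance
   geometry under lower/upper bounds built from the initial geometry plus
   covalent and van-der-Waals radii. Multidentate ligands are embedded with
   the metal and site targets inside the bounds matrix so the conformer
   spans its binding site. The Kabsch algorithm rotates each conformer
   about the metal onto its assigned sites, recording the rotational RMSD
   (rotRMSD).
4. **Assembly and relaxation.** Ligands are added greedily from highest to
   lowest denticity; at each step the candidate minimizing
   `energy × (1 / max(rotRMSD, 0.01 Å))` among those passing interatomic
   distance pre-checks is kept. Assembled complexes are relaxed with a
   pluggable calculator (any object with `evaluate`/`relax`/`supports`
   works; the built-in scaffold potential combines harmonic bonds, a
   Kepert-style repulsion between coordinated atoms, Lennard-Jones and
   Coulomb nonbonded terms), then checked for graph fidelity.
5. **Ranking and deduplication.** Output conformers are ranked by energy;
   duplicates are removed with the Kuhn–Munkres ordered RMSD (kmRMSD — the
   RMSD minimized jointly over rigid superposition and optimal same-element
   atom assignment) at a 0.5 Å threshold. The metal-proximal variant
   c-kmRMSD, restricted to atoms within two bond hops of the metal, is
   exposed for structure comparison where distal ligand tails would drown
   out the coordination geometry.

Actinide metal centers are transparently swapped for their same-group
lanthanide (Th→Ce, U→Nd, …) when a calculator backend does not support
Z > 88; the swap preserves the f-electron count at the requested oxidation
state.

## Worked example

```python
from metallobuild import BuildRequest, LigandInput, build_complex

request = BuildRequest(
    metal="Fe",
    ligands=[LigandInput("O", ca_indices=(0,), count=6)],
    seed=7,
)
result = build_complex(request)
for k, conf in enumerate(result.conformers):
    print(f"rank {k}: E = {conf.energy:.2f} kcal/mol, "
          f"start core = {conf.provenance['core']}, sane = {conf.sane}")
print("attrition:", result.report.counts)
```

prints

```
rank 0: E = -1672.76 kcal/mol, start core = trigonal_prismatic, sane = True
attrition: {'ligand_conformers_generated': 18, 'cores_considered': 2,
 'assignments_enumerated': 1440, 'assignments_unique': 2,
 'assignments_selected': 2, 'assemblies_attempted': 2, 'assembled': 2,
 'skipped_relaxation': 0, 'duplicates_removed': 1, 'survivors': 1}
```

Both CN 6 starting symmetries (octahedral and trigonal prismatic) were
assembled; under the scaffold potential the trigonal prism relaxes into the
octahedron, so the two conformers become kmRMSD duplicates and a single
octahedral Fe(H₂O)₆³⁺ survives. Its O–Fe–O angle multiset is
{90°×12, 180°×3} to within a degree. The energy is the scaffold-potential
total (including per-atom reference energies); only differences between
conformers of the same complex are meaningful.

The same build from the command line, for a mixed-denticity Ce(III)
complex (tridentate diethylenetriamine + bidentate ethylenediamine +
water):

```bash
metallobuild build --metal Ce \
    --ligand "NCCNCCN:0,3,6" --ligand "NCCN:0,3" --ligand "O:0" \
    --seed 11 --output ce.xyz --report ce.json
# 1 conformer(s) written to ce.xyz; best energy -3416.8316 (octahedral)

metallobuild compare ce.xyz ce.xyz
# kmRMSD          0.0000 Å
# c-kmRMSD(d=2)   0.0000 Å
```

`metallobuild fixtures` lists the built-in toy complexes (hexaaqua Fe,
CN 8/CN 9 lanthanide cores, a mixed-denticity Ce complex) and can emit any
of them as a request JSON plus an idealized reference XYZ.

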