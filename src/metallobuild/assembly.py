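"""Full-complex assembly, sanity checking, relaxation and ranked output.

:func:`build_complex` orchestrates the whole 2D-to-3D pipeline:

    defaults -> core geometries -> ligand typing -> site mapping
    (pseudo-energy top-N per core) -> ligand distance-geometry conformers
    -> greedy assembly (highest denticity first, energy x 1/rotRMSD bias)
    -> pre-evaluation distance checks -> relaxation of the top candidates
    -> post-relaxation graph-fidelity checks -> kmRMSD duplicate removal
    -> ascending-energy ranked conformers with full provenance.

Every stage keeps attrition counts in a :class:`BuildReport`; the identity
(attempted = survivors + sum of per-stage rejections) is asserted on every
build.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calculators import CalculatorContract, ScaffoldCalculator
from .compare import AtomSet, remove_duplicates
from .elements import (
    ElectronicState,
    actinide_proxy,
    assign_defaults,
    covalent_radius,
    vdw_radius,
)
from .errors import (
    AssemblyInfeasibleError,
    BuildFailedError,
    EmbeddingError,
    CleaningError,
    ImpossiblePlacementError,
    MetallobuildError,
    RelaxationError,
)
from .geometries import classify_ligand_type, list_core_geometries
from .ligand3d import (
    LigandGraph,
    PlacedLigand,
    build_bounds,
    clean_geometry,
    conform_to_sites,
    embed_constrained,
    embed_distance_geometry,
    kabsch_align,
    place_ligand,
    prepare_ligand,
)
from .mapping import (
    BindingAssignment,
    deduplicate_assignments,
    enumerate_assignments,
    enumerate_binding_sites,
    rank_assignments,
)

__all__ = [
    "LigandInput",
    "BuildRequest",
    "Conformer",
    "BuildReport",
    "BuildResult",
    "SanityParams",
    "assemble",
    "sanity_check",
    "relax",
    "build_complex",
    "ROT_RMSD_FLOOR",
]

ROT_RMSD_FLOOR = 0.01  # Å floor in the 1/rotRMSD selection bias

# pre-evaluation / post-relaxation distance-check constants (reconstructions,
# pinned here; see the methods note)
@dataclass(frozen=True)
class SanityParams:
    c1_interligand_vdw: float = 0.6
    c2_nonbonded_rcov: float = 0.65
    c3_ca_window: float = 0.45  # Å
    bond_window: tuple[float, float] = (0.7, 1.3)


@dataclass
class LigandInput:
    """One ligand recipe: SMILES, 0-based heavy-atom CA indices, multiplicity."""

    smiles: str
    ca_indices: tuple[int, ...]
    count: int = 1
    name: Optional[str] = None

    def __post_init__(self):
        self.ca_indices = tuple(int(i) for i in self.ca_indices)
        if self.count < 1:
            raise ValueError("ligand count must be >= 1")

    @property
    def label(self) -> str:
        return self.name or f"{self.smiles}|{','.join(map(str, self.ca_indices))}"


@dataclass
class BuildRequest:
    """The full 2D specification of a construction job."""

    metal: str
    ligands: list[LigandInput]
    metal_oxidation: Optional[int] = None
    spin_multiplicity: Optional[int] = None
    cn: Optional[int] = None
    seed: int = 0


@dataclass
class Conformer:
    """One assembled/relaxed 3D realization of the requested 2D graph."""

    elements: list[str]
    coordinates: np.ndarray
    total_charge: int
    spin_multiplicity: int
    energy: float
    calculator: str
    provenance: dict
    graph: list[tuple[int, int, float]]
    formal_charges: list[float]
    metal_index: int = 0
    ligand_ranges: list[tuple[int, int]] = field(default_factory=list)
    ca_info: list[tuple[int, float]] = field(default_factory=list)  # (atom, target Å)
    sane: bool = True
    failure_reason: Optional[str] = None

    def to_atom_set(self) -> AtomSet:
        return AtomSet(
            elements=list(self.elements),
            coordinates=np.asarray(self.coordinates),
            graph=[(i, j) for i, j, _ in self.graph],
            metal_index=self.metal_index,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class BuildReport:
    """Per-stage attrition accounting for one build."""

    parameters: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    failure_reasons: list[str] = field(default_factory=list)

    def bump(self, key: str, n: int = 1):
        self.counts[key] = self.counts.get(key, 0) + n

    def balanced(self) -> bool:
        c = self.counts
        return c.get("assembled", 0) == (
            c.get("survivors", 0)
            + c.get("skipped_relaxation", 0)
            + c.get("pre_eval_failed", 0)
            + c.get("relaxation_failed", 0)
            + c.get("post_relax_failed", 0)
            + c.get("duplicates_removed", 0)
        )


@dataclass
class BuildResult:
    conformers: list[Conformer]
    report: BuildReport
    assembled: Optional[list[Conformer]] = None


# ---------------------------------------------------------------------------
# sanity checks

def _pairwise_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)


def sanity_check(
    conformer: Conformer,
    stage: str,
    params: SanityParams = SanityParams(),
) -> tuple[bool, Optional[str]]:
    """Staged interatomic-distance sanity checks.

    ``pre_eval`` applies three cutoff checks that weed out unreasonable
    geometries before any energy evaluation: (1) inter-ligand contacts
    against scaled vdW sums, (2) non-bonded intra-complex contacts against
    scaled covalent sums, (3) every coordinating atom within a window of
    its target metal-CA length. ``post_relax`` additionally verifies the 3D
    structure still matches the input 2D graph: bonded pairs inside a
    [0.7, 1.3] x (rcov sum) window and no non-CA atom closer to the metal
    than its nearest coordinating atom. Returns (sane, first failed rule).
    """
    if stage not in ("pre_eval", "post_relax"):
        raise ValueError(f"unknown stage {stage!r}")
    coords = np.asarray(conformer.coordinates, dtype=float)
    if not np.all(np.isfinite(coords)):
        return False, "non_finite_coordinates"
    els = conformer.elements
    n = len(els)
    rcov = np.array([covalent_radius(el) for el in els])
    vdw = np.array([vdw_radius(el) for el in els])
    bonded = {(min(i, j), max(i, j)) for i, j, _ in conformer.graph}
    m = conformer.metal_index

    lig_id = np.full(n, -1)
    for k, (a, b) in enumerate(conformer.ligand_ranges):
        lig_id[a:b] = k

    d = _pairwise_dists(coords, coords)

    # (1) inter-ligand minimum distances
    for i in range(n):
        for j in range(i + 1, n):
            if lig_id[i] < 0 or lig_id[j] < 0 or lig_id[i] == lig_id[j]:
                continue
            if d[i, j] < params.c1_interligand_vdw * (vdw[i] + vdw[j]):
                return False, "inter_ligand_clash"
    # (2) non-bonded intra-complex contacts
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            if d[i, j] < params.c2_nonbonded_rcov * (rcov[i] + rcov[j]):
                return False, "nonbonded_contact"
    # (3) CA within window of its target metal-CA length
    for ca, target in conformer.ca_info:
        if abs(d[m, ca] - target) > params.c3_ca_window:
            return False, "ca_displaced"

    if stage == "post_relax":
        lo, hi = params.bond_window
        for i, j, _ in conformer.graph:
            ref = rcov[i] + rcov[j]
            if not (lo * ref <= d[i, j] <= hi * ref):
                return False, "bond_broken"
        ca_atoms = {ca for ca, _ in conformer.ca_info}
        if ca_atoms:
            # heavy atoms three or more bonds from the metal have no
            # geometric business near it: anything closer than the nearest
            # bonded CA is a new (graph-violating) metal contact. One- and
            # two-bond neighbors are exempt (their proximity is forced by
            # the coordination geometry), as are hydrogens — chelate
            # backbone C-H routinely dips just inside the CA sphere on
            # large metals without any bonding interaction.
            adj = [[] for _ in range(n)]
            for i, j, _ in conformer.graph:
                adj[i].append(j)
                adj[j].append(i)
            hops = {m: 0}
            frontier = [m]
            while frontier:
                nxt = []
                for u in frontier:
                    if hops[u] >= 2:
                        continue
                    for v in adj[u]:
                        if v not in hops:
                            hops[v] = hops[u] + 1
                            nxt.append(v)
                frontier = nxt
            min_ca = min(d[m, ca] for ca in ca_atoms)
            for i in range(n):
                if i == m or els[i] == "H" or hops.get(i, 3) <= 2:
                    continue
                if d[m, i] < min_ca:
                    return False, "new_metal_contact"
    return True, None


# ---------------------------------------------------------------------------
# assembly

def _placement_ok(
    pl: PlacedLigand,
    metal_rcov: float,
    existing_coords: np.ndarray,
    existing_vdw: np.ndarray,
    params: SanityParams,
) -> bool:
    """Distance pre-checks for one candidate against the partial complex."""
    coords = pl.coordinates
    vdw = np.array([vdw_radius(el) for el, _ in pl.ligand.atoms])
    rcov = np.array([covalent_radius(el) for el, _ in pl.ligand.atoms])
    # CA window vs its own target
    for k, ca in enumerate(pl.ca_order):
        target = np.linalg.norm(pl.ca_targets[k])
        if abs(np.linalg.norm(coords[ca]) - target) > params.c3_ca_window:
            return False
    # non-CA atoms must stay off the metal (origin)
    ca_set = set(pl.ca_order)
    for i in range(len(coords)):
        if i in ca_set:
            continue
        if np.linalg.norm(coords[i]) < params.c2_nonbonded_rcov * (
            metal_rcov + rcov[i]
        ):
            return False
    # against previously placed ligands (existing excludes the metal row)
    if len(existing_coords):
        d = _pairwise_dists(coords, existing_coords)
        limit = params.c1_interligand_vdw * (vdw[:, None] + existing_vdw[None, :])
        if np.any(d < limit):
            return False
    return True


def assemble(
    assignment: BindingAssignment,
    ligand_conformers: Sequence[Sequence[PlacedLigand]],
    calculator: CalculatorContract,
    metal: str,
    state: ElectronicState,
    params: SanityParams = SanityParams(),
    rot_rmsd_floor: float = ROT_RMSD_FLOOR,
) -> Conformer:
    """Greedy ligand-by-ligand assembly of one binding assignment.

    Ligands are added from highest to lowest denticity (ties: more heavy
    atoms first, then input order). At each step, candidates that fail the
    distance pre-checks are discarded; among the survivors the conformer
    minimizing total energy x (1 / max(rotRMSD, floor)) is kept, biasing
    choices toward well-aligned, low-energy placements. If every candidate
    for some ligand fails, :class:`AssemblyInfeasibleError` carries that
    ligand's index.
    """
    n_lig = len(ligand_conformers)
    order = sorted(
        range(n_lig),
        key=lambda k: (
            -ligand_conformers[k][0].ligand.denticity,
            -ligand_conformers[k][0].ligand.n_heavy,
            k,
        ),
    )
    metal_rcov = covalent_radius(metal)

    elements: list[str] = [metal]
    coords_list: list[np.ndarray] = [np.zeros((1, 3))]
    formal_charges: list[float] = [float(state.metal_oxidation)]
    graph: list[tuple[int, int, float]] = []
    ligand_ranges: list[tuple[int, int]] = []
    ca_info: list[tuple[int, float]] = []
    chosen: list[PlacedLigand] = []

    existing = np.zeros((0, 3))
    existing_vdw = np.zeros((0,))
    n_atoms = 1

    for k in order:
        candidates = ligand_conformers[k]
        viable = [
            pl
            for pl in candidates
            if _placement_ok(pl, metal_rcov, existing, existing_vdw, params)
        ]
        if not viable:
            raise AssemblyInfeasibleError(
                f"no candidate conformer for ligand {k} passed placement checks",
                ligand_index=k,
            )
        best = None
        for pl in viable:
            trial_elements = elements + [el for el, _ in pl.ligand.atoms]
            trial_coords = np.vstack(coords_list + [pl.coordinates])
            trial_graph = list(graph)
            off = n_atoms
            for i, j, o in pl.ligand.bonds:
                trial_graph.append((i + off, j + off, o))
            for ca in pl.ca_order:
                trial_graph.append((0, ca + off, 1.0))
            trial_q = formal_charges + [float(q) for _, q in pl.ligand.atoms]
            energy = calculator.evaluate(
                trial_elements,
                trial_coords,
                charge=state.total_charge,
                multiplicity=state.spin_multiplicity,
                graph=trial_graph,
                formal_charges=trial_q,
            )
            score = energy / max(pl.rot_rmsd, rot_rmsd_floor)
            if best is None or score < best[0] - 1e-12:
                best = (score, pl)
        _, pl = best
        off = n_atoms
        elements.extend(el for el, _ in pl.ligand.atoms)
        coords_list.append(pl.coordinates)
        formal_charges.extend(float(q) for _, q in pl.ligand.atoms)
        for i, j, o in pl.ligand.bonds:
            graph.append((i + off, j + off, o))
        for idx, ca in enumerate(pl.ca_order):
            graph.append((0, ca + off, 1.0))
            ca_info.append((ca + off, float(np.linalg.norm(pl.ca_targets[idx]))))
        ligand_ranges.append((off, off + pl.ligand.n_atoms))
        chosen.append(pl)
        n_atoms += pl.ligand.n_atoms
        existing = np.vstack([existing, pl.coordinates])
        existing_vdw = np.concatenate(
            [existing_vdw, [vdw_radius(el) for el, _ in pl.ligand.atoms]]
        )

    coordinates = np.vstack(coords_list)
    energy = calculator.evaluate(
        elements,
        coordinates,
        charge=state.total_charge,
        multiplicity=state.spin_multiplicity,
        graph=graph,
        formal_charges=formal_charges,
    )
    return Conformer(
        elements=elements,
        coordinates=coordinates,
        total_charge=state.total_charge,
        spin_multiplicity=state.spin_multiplicity,
        energy=float(energy),
        calculator=calculator.name,
        provenance={
            "core": assignment.core.name,
            "assignment": assignment.to_record(),
            "ligand_order": order,
            "seeds": [pl.source_seed for pl in chosen],
            "rot_rmsds": [pl.rot_rmsd for pl in chosen],
        },
        graph=graph,
        formal_charges=formal_charges,
        ligand_ranges=ligand_ranges,
        ca_info=ca_info,
    )


def relax(
    conformer: Conformer,
    calculator: CalculatorContract,
    max_steps: int = 300,
) -> Conformer:
    """Relax an assembled conformer with the calculator's optimizer.

    The returned conformer keeps full provenance; non-convergence within
    ``max_steps`` is flagged in provenance rather than raised (the best
    coordinates so far are returned). Energy never increases.
    """
    try:
        coords, energy, converged = calculator.relax(
            conformer.elements,
            conformer.coordinates,
            charge=conformer.total_charge,
            multiplicity=conformer.spin_multiplicity,
            graph=conformer.graph,
            formal_charges=conformer.formal_charges,
            max_steps=max_steps,
        )
    except Exception as exc:
        raise RelaxationError(f"calculator failed during relaxation: {exc}") from exc
    provenance = dict(conformer.provenance)
    provenance["relax_converged"] = bool(converged)
    return Conformer(
        elements=list(conformer.elements),
        coordinates=np.asarray(coords),
        total_charge=conformer.total_charge,
        spin_multiplicity=conformer.spin_multiplicity,
        energy=float(energy),
        calculator=calculator.name,
        provenance=provenance,
        graph=list(conformer.graph),
        formal_charges=list(conformer.formal_charges),
        metal_index=conformer.metal_index,
        ligand_ranges=list(conformer.ligand_ranges),
        ca_info=list(conformer.ca_info),
    )


# ---------------------------------------------------------------------------
# orchestration

def _derive_seed(master: int, *indices: int) -> int:
    s = (int(master) * 1_000_003 + 12_345) % (2**31 - 1)
    for ix in indices:
        s = (s * 69_069 + int(ix) + 1) % (2**31 - 1)
    return s


def build_complex(
    request: BuildRequest,
    calculator: Optional[CalculatorContract] = None,
    n_conformers_per_ligand: int = 3,
    top_n_assignments: int = 10,
    max_core_geometries: int = 20,
    relax_top: int = 10,
    relax_max_steps: int = 300,
    angle_tolerance: float = 15.0,
    dedup_threshold: float = 0.5,
    sanity: SanityParams = SanityParams(),
    return_assembled: bool = False,
) -> BuildResult:
    """Run the full 2D-to-3D pipeline for one build request.

    Defaults mirror the standard operating point: up to 20 core symmetries,
    the 10 lowest-pseudo-energy binding assignments per core, 3
    distance-geometry conformers per ligand, the top 10 assembled complexes
    relaxed, duplicates removed at 0.5 Å full kmRMSD. Raises
    :class:`BuildFailedError` (carrying the attrition report) if nothing
    survives, or :class:`ImpossiblePlacementError` before any 3D work when
    the total denticity exceeds the coordination number.
    """
    calculator = calculator or ScaffoldCalculator()
    report = BuildReport(
        parameters={
            "metal": request.metal,
            "seed": request.seed,
            "n_conformers_per_ligand": n_conformers_per_ligand,
            "top_n_assignments": top_n_assignments,
            "max_core_geometries": max_core_geometries,
            "relax_top": relax_top,
            "dedup_threshold": dedup_threshold,
            "calculator": calculator.name,
        }
    )

    metal = request.metal
    if not calculator.supports(metal):
        proxied = actinide_proxy(metal)
        if proxied == metal or not calculator.supports(proxied):
            raise MetallobuildError(
                f"calculator {calculator.name!r} does not support {metal}"
            )
        report.parameters["actinide_proxy"] = f"{metal}->{proxied}"
        metal = proxied

    # expand ligand recipes into instances, prepare each unique recipe once
    prepared: dict[str, tuple[LigandGraph, np.ndarray]] = {}
    instances: list[tuple[str, LigandGraph, np.ndarray]] = []
    for recipe in request.ligands:
        key = recipe.label
        if key not in prepared:
            prepared[key] = prepare_ligand(recipe.smiles, recipe.ca_indices)
        for _ in range(recipe.count):
            graph, coords = prepared[key]
            instances.append((key, graph, coords))
    if not instances:
        raise BuildFailedError("request contains no ligands", report)
    labels = [key for key, _, _ in instances]

    state = assign_defaults(
        metal,
        ligand_charges=[g.formal_charge for _, g, _ in instances],
        overrides={
            k: v
            for k, v in (
                ("metal_oxidation", request.metal_oxidation),
                ("spin_multiplicity", request.spin_multiplicity),
            )
            if v is not None
        },
    )

    total_denticity = sum(g.denticity for _, g, _ in instances)
    cn = request.cn if request.cn is not None else total_denticity
    if total_denticity > cn:
        raise ImpossiblePlacementError(
            f"total denticity {total_denticity} exceeds CN {cn}"
        )

    # ligand typing from the prepared geometry's CA-CA separations
    lig_types = []
    for key, g, coords in instances:
        if g.denticity == 1:
            lig_types.append(classify_ligand_type(1))
            continue
        estimates = []
        cas = list(g.ca_indices)
        for a in range(len(cas)):
            for b in range(a + 1, len(cas)):
                ra = covalent_radius(metal) + covalent_radius(g.atoms[cas[a]][0])
                rb = covalent_radius(metal) + covalent_radius(g.atoms[cas[b]][0])
                bite = float(np.linalg.norm(coords[cas[a]] - coords[cas[b]]))
                cos = np.clip((ra**2 + rb**2 - bite**2) / (2 * ra * rb), -1, 1)
                estimates.append(float(np.degrees(np.arccos(cos))))
        lig_types.append(classify_ligand_type(g.denticity, estimates))

    # distance-geometry conformers per ligand instance
    conformer_pool: list[list[np.ndarray]] = []
    for li, (key, g, init_coords) in enumerate(instances):
        if g.n_atoms == 1:
            conformer_pool.append([init_coords.copy()])
            continue
        bounds = build_bounds(g, init_coords)
        pool: list[np.ndarray] = []
        for k in range(n_conformers_per_ligand):
            seed = _derive_seed(request.seed, li, k)
            try:
                embedded = embed_distance_geometry(bounds, seed)
                cleaned = clean_geometry(g, embedded)
            except (EmbeddingError, CleaningError):
                report.bump("ligand_conformers_failed")
                continue
            pool.append(cleaned)
            report.bump("ligand_conformers_generated")
        if not pool:
            raise BuildFailedError(
                f"no 3D conformer could be generated for ligand {key!r}", report
            )
        conformer_pool.append(pool)

    # site mapping per core geometry
    cores = list_core_geometries(cn)[:max_core_geometries]
    report.counts["cores_considered"] = len(cores)
    selected: list[BindingAssignment] = []
    for core in cores:
        sites_per_ligand = []
        for li, t in enumerate(lig_types):
            sites_per_ligand.append(
                enumerate_binding_sites(
                    core, t, angle_tolerance=angle_tolerance, ligand_index=li
                )
            )
        assignments = enumerate_assignments(core, sites_per_ligand)
        report.bump("assignments_enumerated", len(assignments))
        unique = deduplicate_assignments(assignments, labels)
        report.bump("assignments_unique", len(unique))
        selected.extend(rank_assignments(unique, top_n=top_n_assignments))
    report.counts["assignments_selected"] = len(selected)
    if not selected:
        raise BuildFailedError(
            "no conflict-free core-ligand mapping exists for this request", report
        )

    # assemble every selected assignment
    m_rcov = covalent_radius(metal)
    assembled: list[Conformer] = []
    chelate_cache: dict = {}

    def _chelate_candidates(li: int, site, core) -> list[PlacedLigand]:
        """Site-constrained DG conformers for a multidentate ligand.

        The metal and the site targets enter the bounds matrix, so the
        generated geometry already spans the site; a UFF polish with the
        CAs pinned absorbs residual strain. Cached per congruent site class.
        """
        g = instances[li][1]
        idx = list(site.core_site_indices)
        lengths = np.array(
            [m_rcov + covalent_radius(g.atoms[ca][0]) for ca in g.ca_indices]
        )
        # pair CAs to sites so ligand CA-CA separations best match chords
        import itertools as _it

        best_perm, best_mis = None, np.inf
        ref = instances[li][2]
        for perm in _it.permutations(range(g.denticity)):
            t = core.site_vectors[idx] * lengths[list(perm), None]
            mis = 0.0
            for a in range(g.denticity):
                for b in range(a + 1, g.denticity):
                    ca_a, ca_b = g.ca_indices[perm[a]], g.ca_indices[perm[b]]
                    mis += abs(
                        np.linalg.norm(ref[ca_a] - ref[ca_b])
                        - np.linalg.norm(t[a] - t[b])
                    )
            if mis < best_mis - 1e-12:
                best_perm, best_mis = perm, mis
        perm = best_perm
        ca_order = tuple(g.ca_indices[p] for p in perm)
        targets = core.site_vectors[idx] * lengths[list(perm), None]
        sig = (
            li,
            tuple(np.round(np.linalg.norm(targets, axis=1), 6)),
            tuple(
                np.round(
                    sorted(
                        np.linalg.norm(targets[a] - targets[b])
                        for a in range(len(idx))
                        for b in range(a + 1, len(idx))
                    ),
                    6,
                )
            ),
        )
        cached = chelate_cache.get(sig)
        if cached is None:
            cached = []
            rcov_lig = np.array(
                [covalent_radius(el) for el, _ in g.atoms]
            )
            clearance = 0.7 * (m_rcov + rcov_lig)  # metal-free FF guard
            non_ca = np.array(
                [i for i in range(g.n_atoms) if i not in set(ca_order)],
                dtype=int,
            )
            for k in range(n_conformers_per_ligand):
                seed = _derive_seed(request.seed, li, k)
                try:
                    lig_coords, _ = embed_constrained(
                        g, instances[li][2], ca_order, targets, metal, seed
                    )
                except EmbeddingError:
                    report.bump("placements_failed")
                    continue
                try:
                    polished = conform_to_sites(g, lig_coords, ca_order, targets)
                    radii = np.linalg.norm(polished[non_ca], axis=1)
                    if len(non_ca) == 0 or np.all(
                        radii >= clearance[non_ca]
                    ):
                        lig_coords = polished
                except CleaningError:
                    pass  # keep the unpolished embedding
                cached.append((seed, lig_coords))
            chelate_cache[sig] = cached
        out = []
        for seed, lig_coords in cached:
            # rotate the cached (congruent) geometry onto this site's frame
            R, rmsd = kabsch_align(
                np.asarray(lig_coords)[list(ca_order)], targets
            )
            out.append(
                PlacedLigand(
                    coordinates=np.asarray(lig_coords) @ R.T,
                    rot_rmsd=float(rmsd),
                    source_seed=seed,
                    ligand=g,
                    site=site,
                    ca_order=ca_order,
                    ca_targets=targets,
                )
            )
        return out

    for ai, assignment in enumerate(selected):
        per_ligand: list[list[PlacedLigand]] = []
        for li, site in enumerate(assignment.sites):
            g = instances[li][1]
            if g.denticity > 1:
                per_ligand.append(
                    _chelate_candidates(li, site, assignment.core)
                )
                continue
            lengths = [
                m_rcov + covalent_radius(g.atoms[ca][0]) for ca in g.ca_indices
            ]
            placed = []
            for k, pool_coords in enumerate(conformer_pool[li]):
                pl = place_ligand(
                    g,
                    pool_coords,
                    site,
                    assignment.core,
                    lengths,
                    source_seed=_derive_seed(request.seed, li, k),
                )
                placed.append(pl)
            per_ligand.append(placed)
        report.bump("assemblies_attempted")
        if any(not cands for cands in per_ligand):
            report.bump("assemblies_failed")
            report.failure_reasons.append("assembly:no_conformable_placement")
            continue
        try:
            conf = assemble(
                assignment, per_ligand, calculator, metal, state, params=sanity
            )
        except AssemblyInfeasibleError as exc:
            report.bump("assemblies_failed")
            report.failure_reasons.append(f"assembly:{exc.ligand_index}")
            continue
        assembled.append(conf)
    report.counts["assembled"] = len(assembled)
    if not assembled:
        raise BuildFailedError("every assembly attempt failed", report)

    assembled.sort(key=lambda c: c.energy)

    # relax the lowest-energy candidates, verify, deduplicate
    survivors: list[Conformer] = []
    to_relax = assembled[: max(relax_top, 0)]
    report.bump("skipped_relaxation", len(assembled) - len(to_relax))
    for conf in to_relax:
        ok, reason = sanity_check(conf, "pre_eval", sanity)
        if not ok:
            conf.sane, conf.failure_reason = False, reason
            report.bump("pre_eval_failed")
            report.failure_reasons.append(f"pre_eval:{reason}")
            continue
        try:
            relaxed = relax(conf, calculator, max_steps=relax_max_steps)
        except RelaxationError:
            report.bump("relaxation_failed")
            continue
        ok, reason = sanity_check(relaxed, "post_relax", sanity)
        if not ok:
            relaxed.sane, relaxed.failure_reason = False, reason
            report.bump("post_relax_failed")
            report.failure_reasons.append(f"post_relax:{reason}")
            continue
        survivors.append(relaxed)

    kept = remove_duplicates(survivors, threshold=dedup_threshold)
    report.bump("duplicates_removed", len(survivors) - len(kept))
    report.counts["survivors"] = len(kept)
    assert report.balanced(), "attrition accounting does not balance"

    if not kept:
        raise BuildFailedError(
            "no conformer survived relaxation and sanity checks", report
        )
    kept.sort(key=lambda c: c.energy)
    return BuildResult(
        conformers=kept,
        report=report,
        assembled=assembled if return_assembled else None,
    )
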