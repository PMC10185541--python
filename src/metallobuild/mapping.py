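"""Core-ligand binding-site mapping, ranking and deduplication.

Given a coordination polyhedron and the coordination type of every ligand,
this module enumerates where each ligand's coordinating atoms (CAs) can sit
on the core (angle matching), combines per-ligand options into conflict-free
assignments (no shared core sites), removes assignments equivalent under
permutation of identical ligands, and ranks the survivors by a cheap
Coulomb-like pseudo-energy so that only the most promising mappings go on to
expensive 3D work.

The pseudo-energy places a heuristic charge ``b`` (default 1) on every
occupied site and sums ``b_i * b_j / d_ij`` over occupied-site pairs, where
``d_ij`` is the chord distance between the unit site vectors. Like charges
spread out, so trans/even arrangements score lower (better) than crowded
ones. The functional form is a reconstruction — documented in the methods
note — and the charge vector is user-overridable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateInputError, ImpossiblePlacementError
from .geometries import CoreGeometry, LigandType, match_angle_sets

__all__ = [
    "BindingSite",
    "BindingAssignment",
    "enumerate_binding_sites",
    "enumerate_assignments",
    "deduplicate_assignments",
    "pseudo_energy",
    "rank_assignments",
    "core_symmetry_operations",
    "DEFAULT_ANGLE_TOLERANCE",
    "DEFAULT_RAW_CAP",
]

DEFAULT_ANGLE_TOLERANCE = 15.0  # degrees
DEFAULT_RAW_CAP = 1_000_000
_BEAM_WIDTH = 10_000


@dataclass(frozen=True)
class BindingSite:
    """One way to put a single ligand's CAs onto core sites."""

    ligand_index: int
    core_site_indices: tuple[int, ...]
    angular_deviation: float  # summed |Δangle| vs the ligand type, degrees

    def __post_init__(self):
        if len(set(self.core_site_indices)) != len(self.core_site_indices):
            raise ValueError("core site indices must be distinct")
        if self.angular_deviation < 0:
            raise ValueError("angular deviation must be >= 0")


@dataclass(frozen=True)
class BindingAssignment:
    """A conflict-free placement of every ligand, with its pseudo-energy."""

    core: CoreGeometry
    sites: tuple[BindingSite, ...]
    pseudo_energy: float

    @property
    def occupied(self) -> tuple[int, ...]:
        return tuple(i for s in self.sites for i in s.core_site_indices)

    @property
    def angular_deviation(self) -> float:
        return sum(s.angular_deviation for s in self.sites)

    def site_tuples(self) -> tuple[tuple[int, ...], ...]:
        return tuple(s.core_site_indices for s in self.sites)

    def to_record(self) -> dict:
        """JSON-serializable record for reproducibility/debugging."""
        return {
            "core": self.core.name,
            "sites": [list(s.core_site_indices) for s in self.sites],
            "pseudo_energy": self.pseudo_energy,
        }


def enumerate_binding_sites(
    core: CoreGeometry,
    ligand_type: LigandType,
    angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE,
    ligand_index: int = 0,
) -> list[BindingSite]:
    """All site combinations whose angle pattern matches the ligand type.

    Every combination of ``denticity`` core sites is tested: its pairwise
    CA-M-CA angle multiset must match the type's template under the optimal
    bipartite pairing with every matched pair within ``angle_tolerance``
    degrees. Monodentate ligands match every site with zero deviation.
    Output is deterministic (lexicographic in site indices).
    """
    d = ligand_type.denticity
    if d > core.cn:
        raise ImpossiblePlacementError(
            f"denticity {d} exceeds core CN {core.cn}"
        )
    angles = core.pair_angles()
    out: list[BindingSite] = []
    for combo in itertools.combinations(range(core.cn), d):
        observed = [
            angles[i, j] for i, j in itertools.combinations(combo, 2)
        ]
        if not observed:
            out.append(BindingSite(ligand_index, combo, 0.0))
            continue
        # max matched deviation gate with summed deviation as the score
        obs = np.asarray(observed)
        tpl = np.asarray(ligand_type.ca_angles)
        total = match_angle_sets(obs, tpl)
        # re-derive the optimal pairing's max deviation
        cost = np.abs(obs[:, None] - tpl[None, :])
        rows, cols = linear_sum_assignment(cost)
        if np.max(cost[rows, cols]) <= angle_tolerance:
            out.append(BindingSite(ligand_index, combo, float(total)))
    return out


def _chord_matrix(core: CoreGeometry) -> np.ndarray:
    v = core.site_vectors
    diff = v[:, None, :] - v[None, :, :]
    return np.linalg.norm(diff, axis=-1)


def pseudo_energy(
    assignment_or_sites,
    heuristic_charges: Optional[Sequence[float]] = None,
    b_default: float = 1.0,
    core: Optional[CoreGeometry] = None,
) -> float:
    """Coulomb-like score of an assignment: sum of b_i*b_j/d_ij over pairs.

    ``heuristic_charges`` gives one charge per ligand (every CA of that
    ligand carries it); the default is ``b_default`` for all. Lower is more
    favorable. Accepts either a :class:`BindingAssignment` or a sequence of
    :class:`BindingSite` plus an explicit ``core``.
    """
    if isinstance(assignment_or_sites, BindingAssignment):
        sites = assignment_or_sites.sites
        core = assignment_or_sites.core
    else:
        sites = tuple(assignment_or_sites)
        if core is None:
            raise ValueError("core required when passing raw sites")
    chord = _chord_matrix(core)
    occupied: list[int] = []
    charges: list[float] = []
    for k, s in enumerate(sites):
        b = (
            float(heuristic_charges[k])
            if heuristic_charges is not None
            else float(b_default)
        )
        for idx in s.core_site_indices:
            occupied.append(idx)
            charges.append(b)
    total = 0.0
    for a in range(len(occupied)):
        for b_ in range(a + 1, len(occupied)):
            d = chord[occupied[a], occupied[b_]]
            if d < 1e-9:
                raise DegenerateInputError(
                    f"coincident occupied sites {occupied[a]}, {occupied[b_]}"
                )
            total += charges[a] * charges[b_] / d
    return float(total)


def enumerate_assignments(
    core: CoreGeometry,
    binding_sites_per_ligand: Sequence[Sequence[BindingSite]],
    heuristic_charges: Optional[Sequence[float]] = None,
    raw_cap: int = DEFAULT_RAW_CAP,
    beam_width: int = _BEAM_WIDTH,
) -> list[BindingAssignment]:
    """All conflict-free combinations of per-ligand binding sites.

    A depth-first product over ligands keeps only combinations whose core
    sites are pairwise disjoint ("no shared core CAs"). If the unpruned
    product exceeds ``raw_cap`` the search degrades to a deterministic
    pseudo-energy-pruned beam (width ``beam_width``) over partial
    assignments, trading completeness for bounded work.

    An empty result is not an error: it signals an infeasible build to the
    caller.
    """
    if any(len(opts) == 0 for opts in binding_sites_per_ligand):
        return []
    chord = _chord_matrix(core)

    def partial_energy(site_list: tuple[BindingSite, ...]) -> float:
        occupied, charges = [], []
        for k, s in enumerate(site_list):
            b = (
                float(heuristic_charges[k])
                if heuristic_charges is not None
                else 1.0
            )
            for idx in s.core_site_indices:
                occupied.append(idx)
                charges.append(b)
        e = 0.0
        for a in range(len(occupied)):
            for bb in range(a + 1, len(occupied)):
                e += charges[a] * charges[bb] / chord[occupied[a], occupied[bb]]
        return e

    results: list[BindingAssignment] = []
    used = [False] * core.cn
    chosen: list[BindingSite] = []
    occupied: list[int] = []  # flat occupied sites with their charges
    charges: list[float] = []

    class _CapExceeded(Exception):
        pass

    def charge_of(k: int) -> float:
        return (
            float(heuristic_charges[k]) if heuristic_charges is not None else 1.0
        )

    def dfs(k: int, energy: float):
        if k == len(binding_sites_per_ligand):
            if len(results) >= raw_cap:
                raise _CapExceeded
            results.append(BindingAssignment(core, tuple(chosen), energy))
            return
        b = charge_of(k)
        for s in binding_sites_per_ligand[k]:
            idxs = s.core_site_indices
            if any(used[i] for i in idxs):
                continue
            # incremental pseudo-energy: new-vs-existing plus internal pairs
            delta = 0.0
            for a, i in enumerate(idxs):
                for o, bo in zip(occupied, charges):
                    delta += b * bo / chord[i, o]
                for j in idxs[a + 1:]:
                    delta += b * b / chord[i, j]
            for i in idxs:
                used[i] = True
                occupied.append(i)
                charges.append(b)
            chosen.append(s)
            dfs(k + 1, energy + delta)
            chosen.pop()
            for i in idxs:
                used[i] = False
                occupied.pop()
                charges.pop()

    try:
        dfs(0, 0.0)
        return results
    except _CapExceeded:
        results.clear()

    # beam fallback: keep the lowest-partial-pseudo-energy prefixes
    beam: list[tuple[float, tuple[BindingSite, ...], frozenset]] = [
        (0.0, (), frozenset())
    ]
    for opts in binding_sites_per_ligand:
        nxt = []
        for energy, prefix, used in beam:
            for s in opts:
                if used & set(s.core_site_indices):
                    continue
                new_prefix = prefix + (s,)
                nxt.append(
                    (
                        partial_energy(new_prefix),
                        new_prefix,
                        used | frozenset(s.core_site_indices),
                    )
                )
        nxt.sort(key=lambda t: (t[0], tuple(s.core_site_indices for s in t[1])))
        beam = nxt[:beam_width]
    return [BindingAssignment(core, prefix, e) for e, prefix, _ in beam]


def _sort_key(a: BindingAssignment):
    return (a.pseudo_energy, a.angular_deviation, a.site_tuples())


def deduplicate_assignments(
    assignments: Sequence[BindingAssignment],
    ligand_identities: Sequence,
    use_core_symmetry: bool = False,
) -> list[BindingAssignment]:
    """Collapse assignments equivalent under permutation of identical ligands.

    Two assignments are duplicates when relabeling ligands that share an
    identity maps one exactly onto the other. With ``use_core_symmetry``
    the equivalence is additionally quotiented by the core's proper
    rotational symmetry operations (off by default: the plain
    identical-ligand reduction is the one whose counting identities —
    n!/C(n, k) — hold). The surviving representative of each class is the
    lowest-pseudo-energy member, ties broken by lexical site tuples; output
    order is canonical (independent of input order).
    """
    if not assignments:
        return []
    symmetry_ops: list[tuple[int, ...]] = [tuple(range(assignments[0].core.cn))]
    if use_core_symmetry:
        symmetry_ops = core_symmetry_operations(assignments[0].core)

    def class_key(a: BindingAssignment):
        best = None
        for perm in symmetry_ops:
            groups: dict = {}
            for s in a.sites:
                label = ligand_identities[s.ligand_index]
                mapped = tuple(sorted(perm[i] for i in s.core_site_indices))
                groups.setdefault(label, []).append(mapped)
            key = tuple(
                sorted((str(label), tuple(sorted(v))) for label, v in groups.items())
            )
            if best is None or key < best:
                best = key
        return best

    classes: dict = {}
    for a in assignments:
        key = class_key(a)
        cur = classes.get(key)
        if cur is None or _sort_key(a) < _sort_key(cur):
            classes[key] = a
    return sorted(classes.values(), key=_sort_key)


def rank_assignments(
    assignments: Sequence[BindingAssignment], top_n: int = 10
) -> list[BindingAssignment]:
    """Ascending pseudo-energy order, truncated to the ``top_n`` best.

    Ties break by summed angular deviation, then lexical site tuples, making
    the ranking a permutation-stable total order.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    return sorted(assignments, key=_sort_key)[:top_n]


@lru_cache(maxsize=64)
def _symmetry_ops_cached(name: str, key: bytes, cn: int) -> tuple[tuple[int, ...], ...]:
    vecs = np.frombuffer(key).reshape(cn, 3)
    angles = np.round(
        np.degrees(
            np.arccos(np.clip(vecs @ vecs.T, -1.0, 1.0))
        ),
        6,
    )
    perms: list[tuple[int, ...]] = []

    def compatible(partial: list[int], cand: int) -> bool:
        k = len(partial)
        return all(
            abs(angles[j, k] - angles[partial[j], cand]) < 1e-4
            for j in range(k)
        )

    def backtrack(partial: list[int], remaining: set):
        if len(partial) == cn:
            # verify realizable by a proper rotation
            P = vecs[list(partial)]
            H = vecs.T @ P
            U, _, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
            if d > 0 and np.allclose(vecs @ R.T, P, atol=1e-6):
                perms.append(tuple(partial))
            return
        for cand in sorted(remaining):
            if compatible(partial, cand):
                backtrack(partial + [cand], remaining - {cand})

    backtrack([], set(range(cn)))
    return tuple(perms)


def core_symmetry_operations(core: CoreGeometry) -> list[tuple[int, ...]]:
    """Site permutations realized by proper rotations of the polyhedron."""
    return list(
        _symmetry_ops_cached(core.name, core.site_vectors.tobytes(), core.cn)
    )
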