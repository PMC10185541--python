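"""Assignment-optimal RMSD metrics and duplicate-conformer removal.

``km_rmsd`` measures the distance between two structures with the same
element multiset as the minimum RMSD over (i) rigid superposition
(rotation + translation, Kabsch) and (ii) optimal re-assignment of atoms
within each element block (Kuhn-Munkres / Hungarian algorithm). The two
subproblems are alternated to convergence from several rotational starts.

``c_km_rmsd`` is the same metric restricted to the chemically decisive
region: atoms within two bond-graph hops of the metal center. Distal
ligand tails dominate a naive full-molecule RMSD while saying little about
the coordination environment; cutting at depth 2 compares what matters.

Note this is deliberately different from the rotation-only rotRMSD used
during ligand placement: km_rmsd superposes freely (translation included),
rotRMSD pivots about the metal only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .elements import covalent_radius
from .errors import IncomparableStructuresError, MetallobuildError

__all__ = [
    "AtomSet",
    "km_rmsd",
    "core_subset",
    "c_km_rmsd",
    "remove_duplicates",
    "perceive_bonds",
    "DUPLICATE_THRESHOLD",
]

DUPLICATE_THRESHOLD = 0.5  # Å, full-kmRMSD duplicate cutoff


@dataclass
class AtomSet:
    """A bare structure: elements, coordinates, optional graph and metal."""

    elements: list[str]
    coordinates: np.ndarray
    graph: Optional[list[tuple[int, int]]] = None
    metal_index: Optional[int] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.elements), 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.graph is not None:
            n = len(self.elements)
            for b in self.graph:
                if not (0 <= b[0] < n and 0 <= b[1] < n):
                    raise ValueError("bond index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def perceive_bonds(atoms: AtomSet, scale: float = 1.25) -> list[tuple[int, int]]:
    """Distance-criterion bond perception: d <= scale * (rcov_i + rcov_j)."""
    coords = atoms.coordinates
    rcov = np.array([covalent_radius(el) for el in atoms.elements])
    bonds = []
    for i in range(atoms.n_atoms):
        for j in range(i + 1, atoms.n_atoms):
            d = np.linalg.norm(coords[i] - coords[j])
            if d <= scale * (rcov[i] + rcov[j]):
                bonds.append((i, j))
    return bonds


def _element_blocks(elements: Sequence[str]) -> dict[str, list[int]]:
    blocks: dict[str, list[int]] = defaultdict(list)
    for i, el in enumerate(elements):
        blocks[el].append(i)
    return dict(blocks)


def _kabsch_full(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation R (applied to centered P) minimizing |P@R.T - Q| after centering."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def _random_rotations(n: int, seed: int = 0) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    rots = [np.eye(3)]
    for _ in range(n):
        A = rng.normal(size=(3, 3))
        Q, R = np.linalg.qr(A)
        Q = Q * np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        rots.append(Q)
    return rots


def _anchor_rotations(
    Ac: np.ndarray,
    Bc: np.ndarray,
    els_a: Sequence[str],
    els_b: Sequence[str],
    max_candidates: int = 40,
) -> list[np.ndarray]:
    """Deterministic rotation starts from candidate anchor-pair alignments.

    Two well-separated reference atoms of A are matched against every
    same-element atom pair of B; each match fixes a rotation (Kabsch on the
    two centered vectors). Exact permuted/rotated copies are always
    recovered from one of these starts, which random restarts alone cannot
    guarantee for symmetric structures.
    """
    n = len(Ac)
    if n < 2:
        return []
    radii = np.linalg.norm(Ac, axis=1)
    a1 = int(np.argmax(radii))
    if radii[a1] < 1e-8:
        return []
    u = Ac[a1] / radii[a1]
    perp = Ac - np.outer(Ac @ u, u)
    a2 = int(np.argmax(np.linalg.norm(perp, axis=1)))
    if np.linalg.norm(perp[a2]) < 1e-8:
        a2 = None  # collinear structure: one anchor suffices

    rb = np.linalg.norm(Bc, axis=1)
    cands = []
    for b1 in range(n):
        if els_b[b1] != els_a[a1]:
            continue
        mis1 = abs(rb[b1] - radii[a1])
        if a2 is None:
            cands.append((mis1, b1, None))
            continue
        for b2 in range(n):
            if b2 == b1 or els_b[b2] != els_a[a2]:
                continue
            mis = mis1 + abs(rb[b2] - radii[a2])
            cands.append((mis, b1, b2))
    cands.sort(key=lambda t: (t[0], t[1], -1 if t[2] is None else t[2]))
    rots = []
    for _, b1, b2 in cands[:max_candidates]:
        if a2 is None or b2 is None:
            P = Bc[[b1]]
            Q = Ac[[a1]]
        else:
            P = Bc[[b1, b2]]
            Q = Ac[[a1, a2]]
        H = P.T @ Q
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        rots.append(Vt.T @ np.diag([1.0, 1.0, d]) @ U.T)
    return rots


def _km_rmsd_directed(
    A: np.ndarray,
    B: np.ndarray,
    blocks_a: dict[str, list[int]],
    blocks_b: dict[str, list[int]],
    els_a: Sequence[str],
    els_b: Sequence[str],
    max_iters: int,
    n_restarts: int,
    tol: float,
    early_exit: float = 1e-9,
) -> float:
    """Min over starts of the alternating assignment/superposition RMSD."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    n = len(Ac)
    best = np.inf
    starts = (
        _random_rotations(n_restarts)
        + _anchor_rotations(Ac, Bc, els_a, els_b)
    )
    for R0 in starts:
        if best <= early_exit:
            break
        Bcur = Bc @ R0.T
        cur_blocks_b = blocks_b  # rows of Bcur follow b's original order
        prev = np.inf
        for _ in range(max_iters):
            # optimal same-element assignment at the current pose
            perm = np.empty(n, dtype=int)
            for el, ia in blocks_a.items():
                ib = cur_blocks_b[el]
                cost = np.sum(
                    (Ac[ia][:, None, :] - Bcur[ib][None, :, :]) ** 2,
                    axis=-1,
                )
                rows, cols = linear_sum_assignment(cost)
                for r, c in zip(rows, cols):
                    perm[ia[r]] = ib[c]
            # permute B into A's order, then rigidly superpose
            Bperm = Bcur[perm]
            Bperm = Bperm - Bperm.mean(axis=0)
            R = _kabsch_full(Bperm, Ac)
            Bcur = Bperm @ R.T
            cur_blocks_b = blocks_a  # rows now aligned to A's indexing
            rmsd = float(np.sqrt(np.mean(np.sum((Bcur - Ac) ** 2, axis=1))))
            if prev - rmsd < tol:
                prev = min(prev, rmsd)
                break
            prev = rmsd
        best = min(best, prev)
    return best


def km_rmsd(
    a: AtomSet,
    b: AtomSet,
    max_iters: int = 50,
    n_restarts: int = 8,
    tol: float = 1e-8,
    include_hydrogens: bool = True,
) -> float:
    """Kuhn-Munkres ordered RMSD between two structures (Å).

    Minimum over rigid superposition and same-element atom assignment of
    the RMSD; symmetric by construction (both directions are evaluated and
    the smaller kept). Raises :class:`IncomparableStructuresError` when the
    element multisets differ.
    """
    els_a, els_b = list(a.elements), list(b.elements)
    A, B = a.coordinates, b.coordinates
    if not include_hydrogens:
        keep_a = [i for i, el in enumerate(els_a) if el != "H"]
        keep_b = [i for i, el in enumerate(els_b) if el != "H"]
        els_a = [els_a[i] for i in keep_a]
        els_b = [els_b[i] for i in keep_b]
        A, B = A[keep_a], B[keep_b]
    if sorted(els_a) != sorted(els_b):
        raise IncomparableStructuresError(
            "structures do not share an element multiset"
        )
    if len(els_a) == 0:
        raise IncomparableStructuresError("empty structures")
    blocks_a = _element_blocks(els_a)
    blocks_b = _element_blocks(els_b)
    fwd = _km_rmsd_directed(
        A, B, blocks_a, blocks_b, els_a, els_b, max_iters, n_restarts, tol
    )
    if fwd <= 1e-9:
        return float(fwd)
    rev = _km_rmsd_directed(
        B, A, blocks_b, blocks_a, els_b, els_a, max_iters, n_restarts, tol
    )
    return float(min(fwd, rev))


def core_subset(a: AtomSet, depth: int = 2) -> AtomSet:
    """Induced substructure of atoms within ``depth`` bond hops of the metal.

    Uses the stored graph when present, otherwise perceives bonds with the
    distance criterion d <= 1.25 * (rcov_i + rcov_j).
    """
    if a.metal_index is None:
        raise MetallobuildError("core_subset requires a metal_index")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    bonds = a.graph if a.graph is not None else perceive_bonds(a)
    n = a.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    for bnd in bonds:
        i, j = int(bnd[0]), int(bnd[1])
        adj[i].append(j)
        adj[j].append(i)
    dist = {a.metal_index: 0}
    frontier = [a.metal_index]
    while frontier:
        nxt = []
        for u in frontier:
            if dist[u] >= depth:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    keep = sorted(dist)
    remap = {old: new for new, old in enumerate(keep)}
    sub_bonds = [
        (remap[i], remap[j])
        for i, j in ((int(b[0]), int(b[1])) for b in bonds)
        if i in dist and j in dist
    ]
    return AtomSet(
        elements=[a.elements[i] for i in keep],
        coordinates=a.coordinates[keep],
        graph=sub_bonds,
        metal_index=remap[a.metal_index],
    )


def c_km_rmsd(a: AtomSet, b: AtomSet, depth: int = 2, **kwargs) -> float:
    """kmRMSD restricted to the depth-limited metal-proximal core."""
    return km_rmsd(core_subset(a, depth), core_subset(b, depth), **kwargs)


def remove_duplicates(
    conformers: Sequence, threshold: float = DUPLICATE_THRESHOLD
) -> list:
    """Greedy duplicate removal by full kmRMSD in ascending-energy order.

    Accepts any objects exposing ``elements``, ``coordinates`` and
    ``energy`` (build Conformers or AtomSet-likes with an energy attribute).
    A conformer is dropped when its full kmRMSD to any retained conformer
    falls below ``threshold``; the retained set keeps ascending energy
    order, so each near-duplicate cluster is represented by its
    lowest-energy member.
    """
    ordered = sorted(conformers, key=lambda c: c.energy)
    retained: list = []
    for cand in ordered:
        cand_set = AtomSet(list(cand.elements), np.asarray(cand.coordinates))
        dup = False
        for kept in retained:
            kept_set = AtomSet(list(kept.elements), np.asarray(kept.coordinates))
            if km_rmsd(cand_set, kept_set) < threshold:
                dup = True
                break
        if not dup:
            retained.append(cand)
    return retained
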