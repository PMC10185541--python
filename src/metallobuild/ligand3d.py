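"""Ligand 3D conformer generation and placement onto core sites.

Pipeline per ligand:

1. :func:`prepare_ligand` — parse the SMILES, add explicit hydrogens and
   produce a force-field-relaxed starting geometry. Coordinating-atom (CA)
   indices are 0-based indices into the heavy-atom order of the input
   SMILES and survive hydrogen addition unchanged (hydrogens are appended
   after the heavy atoms).
2. :func:`build_bounds` — derive lower/upper interatomic distance bounds
   from the starting geometry plus covalent/van-der-Waals radii, then
   triangle-smooth them.
3. :func:`embed_distance_geometry` — sample a distance matrix inside the
   bounds, embed it by metrization + eigenvalue decomposition, and polish
   with a bounds-violation minimizer. Deterministic per seed.
4. :func:`clean_geometry` — multistep force-field cleanup of the embedded
   coordinates (CAs restrained, then free).
5. :func:`place_ligand` — rigidly rotate the ligand about the metal (at the
   origin) so its CAs match the assigned, bond-length-scaled core sites,
   via the Kabsch algorithm; the residual is the rotational RMSD (rotRMSD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from rdkit import Chem
from rdkit.Chem import AllChem

from .elements import vdw_radius
from .errors import (
    CleaningError,
    DisconnectedGraphError,
    EmbeddingError,
    LigandParseError,
)
from .geometries import CoreGeometry
from .mapping import BindingSite

__all__ = [
    "LigandGraph",
    "DistanceBounds",
    "PlacedLigand",
    "prepare_ligand",
    "build_bounds",
    "embed_distance_geometry",
    "embed_constrained",
    "clean_geometry",
    "conform_to_sites",
    "kabsch_align",
    "place_ligand",
    "BOUNDS_DEFAULTS",
]

# reconstruction defaults for the bounds matrices (Å); see methods note
BOUNDS_DEFAULTS = {
    "delta_bond": 0.03,
    "delta_13": 0.10,
    "f_vdw": 0.85,
    "upper_cap": 100.0,
    "eps_dg": 0.35,
    "max_retries": 5,
}


@dataclass
class LigandGraph:
    """Explicit-hydrogen molecular graph of one ligand."""

    atoms: list[tuple[str, int]]  # (element symbol, formal charge)
    bonds: list[tuple[int, int, float]]  # (i, j, order)
    ca_indices: tuple[int, ...]
    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False, default=None)
    ref_coords: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def denticity(self) -> int:
        return len(self.ca_indices)

    @property
    def n_heavy(self) -> int:
        return sum(1 for el, _ in self.atoms if el != "H")

    @property
    def formal_charge(self) -> int:
        return sum(q for _, q in self.atoms)

    def ref_bond_lengths(self) -> dict[tuple[int, int], float]:
        out = {}
        for i, j, _ in self.bonds:
            out[(i, j)] = float(np.linalg.norm(self.ref_coords[i] - self.ref_coords[j]))
        return out

    def topological_distances(self) -> np.ndarray:
        """All-pairs bond-path lengths (hops), via BFS per atom."""
        n = self.n_atoms
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        dist = np.full((n, n), -1, dtype=int)
        for src in range(n):
            dist[src, src] = 0
            queue = [src]
            while queue:
                nxt = []
                for u in queue:
                    for v in adj[u]:
                        if dist[src, v] < 0:
                            dist[src, v] = dist[src, u] + 1
                            nxt.append(v)
                queue = nxt
        return dist


@dataclass
class DistanceBounds:
    """Per-ligand lower/upper interatomic distance matrices (Å)."""

    lower: np.ndarray
    upper: np.ndarray

    def validate(self, tol: float = 1e-9):
        n = self.lower.shape[0]
        if self.lower.shape != (n, n) or self.upper.shape != (n, n):
            raise ValueError("bounds must be square and matching")
        if not np.allclose(self.lower, self.lower.T) or not np.allclose(
            self.upper, self.upper.T
        ):
            raise ValueError("bounds must be symmetric")
        if np.any(np.diag(self.lower) != 0) or np.any(np.diag(self.upper) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.lower > self.upper + tol):
            i, j = np.unravel_index(
                np.argmax(self.lower - self.upper), self.lower.shape
            )
            raise EmbeddingError(
                f"infeasible bounds: lower({i},{j})={self.lower[i, j]:.3f} > "
                f"upper={self.upper[i, j]:.3f}",
                worst_pair=(int(i), int(j)),
                violation=float(self.lower[i, j] - self.upper[i, j]),
            )

    @property
    def n_atoms(self) -> int:
        return self.lower.shape[0]


def prepare_ligand(
    smiles: str, ca_indices: Sequence[int], seed: int = 61_043
) -> tuple[LigandGraph, np.ndarray]:
    """Parse a ligand SMILES into a graph plus a relaxed starting geometry.

    Raises :class:`LigandParseError` for unparsable SMILES or out-of-range
    CA indices, :class:`DisconnectedGraphError` for multi-fragment input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LigandParseError(f"could not parse SMILES {smiles!r}")
    n_heavy = mol.GetNumAtoms()
    ca_indices = tuple(int(i) for i in ca_indices)
    if len(set(ca_indices)) != len(ca_indices):
        raise LigandParseError(f"duplicate CA indices {ca_indices}")
    for i in ca_indices:
        if not 0 <= i < n_heavy:
            raise LigandParseError(
                f"CA index {i} out of range for {n_heavy} heavy atoms"
            )
    if len(Chem.GetMolFrags(mol)) > 1:
        raise DisconnectedGraphError(f"ligand {smiles!r} is disconnected")

    molh = Chem.AddHs(mol)  # hydrogens appended: heavy indices preserved
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(molh, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molh, params) != 0:
            if molh.GetNumAtoms() == 1:
                conf = Chem.Conformer(1)
                conf.SetAtomPosition(0, (0.0, 0.0, 0.0))
                molh.AddConformer(conf)
            else:
                raise LigandParseError(
                    f"failed to embed starting geometry for {smiles!r}"
                )
    if molh.GetNumAtoms() > 1:
        try:
            if AllChem.MMFFHasAllMoleculeParams(molh):
                AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
            else:
                AllChem.UFFOptimizeMolecule(molh, maxIters=500)
        except Exception:  # pragma: no cover - FF setup failures are rare
            pass

    coords = np.array(molh.GetConformer().GetPositions(), dtype=float)
    atoms = [
        (a.GetSymbol(), a.GetFormalCharge()) for a in molh.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in molh.GetBonds()
    ]
    graph = LigandGraph(
        atoms=atoms,
        bonds=bonds,
        ca_indices=ca_indices,
        smiles=smiles,
        mol=molh,
        ref_coords=coords.copy(),
    )
    return graph, coords


def build_bounds(
    ligand: LigandGraph,
    initial_coords: np.ndarray,
    delta_bond: float = BOUNDS_DEFAULTS["delta_bond"],
    delta_13: float = BOUNDS_DEFAULTS["delta_13"],
    f_vdw: float = BOUNDS_DEFAULTS["f_vdw"],
    upper_cap: float = BOUNDS_DEFAULTS["upper_cap"],
) -> DistanceBounds:
    """Distance bounds from the initial geometry plus radii tables.

    Bonded pairs are bracketed tightly around their initial length
    (±``delta_bond``), geminal (1-3) pairs a little looser (±``delta_13``),
    and everything further apart gets a van-der-Waals floor
    ``f_vdw * (vdw_i + vdw_j)`` and a large upper cap. For atom pairs
    sharing a ring the floor is capped by 0.9× the initial distance: ring
    through-space separations (e.g. para carbons of an aromatic ring at
    2.78 Å) legitimately undercut vdW sums, and an uncapped floor would be
    geometrically infeasible. Bounds are then triangle-smoothed.
    """
    coords = np.asarray(initial_coords, dtype=float)
    n = ligand.n_atoms
    topo = ligand.topological_distances()
    if np.any(topo < 0):
        raise DisconnectedGraphError("ligand graph is not connected")
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    vdw = np.array([vdw_radius(el) for el, _ in ligand.atoms])
    rings: list[frozenset] = []
    if ligand.mol is not None:
        rings = [frozenset(r) for r in ligand.mol.GetRingInfo().AtomRings()]

    def same_ring(i, j):
        return any(i in r and j in r for r in rings)

    lower = np.zeros((n, n))
    upper = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if topo[i, j] == 1:
                lo, hi = dmat[i, j] - delta_bond, dmat[i, j] + delta_bond
            elif topo[i, j] == 2:
                lo, hi = dmat[i, j] - delta_13, dmat[i, j] + delta_13
            else:
                lo = f_vdw * (vdw[i] + vdw[j])
                if same_ring(i, j):
                    lo = min(lo, 0.9 * dmat[i, j])
                hi = upper_cap
            lower[i, j] = lower[j, i] = max(lo, 0.0)
            upper[i, j] = upper[j, i] = hi

    # triangle smoothing: shortest-path tightening of uppers, then raise
    # lowers against the smoothed uppers (inverse triangle inequality)
    for k in range(n):
        upper = np.minimum(upper, upper[:, k, None] + upper[None, k, :])
    for k in range(n):
        lower = np.maximum(lower, lower[:, k, None] - upper[None, k, :])
        lower = np.maximum(lower, lower[None, k, :] - upper[:, k, None])
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)

    bounds = DistanceBounds(lower=lower, upper=upper)
    bounds.validate()
    return bounds


def _violation_stats(coords: np.ndarray, bounds: DistanceBounds):
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    over = d - bounds.upper
    under = bounds.lower - d
    viol = np.maximum(np.maximum(over, under), 0.0)
    np.fill_diagonal(viol, 0.0)
    i, j = np.unravel_index(np.argmax(viol), viol.shape)
    return float(viol[i, j]), (int(i), int(j))


def _embed_once(bounds: DistanceBounds, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = bounds.n_atoms
    if n == 1:
        return np.zeros((1, 3))
    u = rng.random((n, n))
    u = np.triu(u, 1)
    u = u + u.T
    dist = bounds.lower + u * (bounds.upper - bounds.lower)
    np.fill_diagonal(dist, 0.0)

    # classical MDS (eigenvalue embedding) of the sampled matrix
    d2 = dist**2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j_mat @ d2 @ j_mat
    evals, evecs = np.linalg.eigh(gram)
    idx = np.argsort(evals)[::-1][:3]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)[None, :]
    if coords.shape[1] < 3:  # pragma: no cover - eigh always returns 3 here
        coords = np.pad(coords, ((0, 0), (0, 3 - coords.shape[1])))

    lo, hi = bounds.lower, bounds.upper

    def objective(x):
        c = x.reshape(n, 3)
        diff = c[:, None, :] - c[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, 1.0)  # avoid 0/0 in gradients; diag excluded anyway
        over = np.maximum(d - hi, 0.0)
        under = np.maximum(lo - d, 0.0)
        np.fill_diagonal(over, 0.0)
        np.fill_diagonal(under, 0.0)
        f = 0.5 * (np.sum(over**2) + np.sum(under**2))  # each pair counted twice
        coef = 2.0 * (over - under) / d
        np.fill_diagonal(coef, 0.0)
        grad = np.einsum("ij,ijk->ik", coef, diff)
        return f, grad.ravel()

    res = minimize(
        objective,
        coords.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    return res.x.reshape(n, 3)


def embed_distance_geometry(
    bounds: DistanceBounds,
    seed: int,
    eps_dg: float = BOUNDS_DEFAULTS["eps_dg"],
    max_retries: int = BOUNDS_DEFAULTS["max_retries"],
) -> np.ndarray:
    """Embed coordinates satisfying the bounds to within ``eps_dg`` (Å).

    Metrization + eigenvalue embedding of a sampled distance matrix,
    polished by L-BFGS minimization of the squared bounds violations.
    Deterministic for a fixed seed; retries with incremented seeds before
    raising :class:`EmbeddingError` carrying the worst violated pair.
    """
    bounds.validate()
    worst = None
    for attempt in range(max_retries):
        coords = _embed_once(bounds, int(seed) + attempt)
        violation, pair = _violation_stats(coords, bounds)
        if violation <= eps_dg:
            return coords
        if worst is None or violation < worst[0]:
            worst = (violation, pair, coords)
    raise EmbeddingError(
        f"embedding failed after {max_retries} attempts; worst violation "
        f"{worst[0]:.3f} Å on atom pair {worst[1]}",
        worst_pair=worst[1],
        violation=worst[0],
    )


def clean_geometry(
    ligand: LigandGraph, coords: np.ndarray, max_its: int = 500
) -> np.ndarray:
    """Multistep force-field cleanup of embedded coordinates.

    Stage 1 minimizes with every coordinating atom positionally fixed
    (preserving the CA arrangement the embedding produced); stage 2 relaxes
    freely. MMFF94 is used where parametrized, UFF otherwise. The result
    must keep every bond within 20% of its prepared reference length, else
    :class:`CleaningError` (the caller discards that conformer). Per-stage
    force-field energy is non-increasing.
    """
    mol = Chem.Mol(ligand.mol)
    if mol.GetNumAtoms() == 1:
        return np.asarray(coords, dtype=float).copy()
    conf = mol.GetConformer()
    coords = np.asarray(coords, dtype=float)
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, coords[i].tolist())

    def get_ff(fix_cas: bool):
        if AllChem.MMFFHasAllMoleculeParams(mol):
            props = AllChem.MMFFGetMoleculeProperties(mol)
            ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        else:
            ff = AllChem.UFFGetMoleculeForceField(mol)
        if ff is None:
            raise CleaningError("force field setup failed")
        if fix_cas:
            for ca in ligand.ca_indices:
                ff.AddFixedPoint(int(ca))
        return ff

    try:
        for fix_cas in (True, False):
            ff = get_ff(fix_cas)
            ff.Initialize()
            e_in = ff.CalcEnergy()
            ff.Minimize(maxIts=max_its)
            e_out = ff.CalcEnergy()
            if e_out > e_in + 1e-6:  # pragma: no cover - FF minimizers descend
                raise CleaningError(
                    f"cleaning stage increased energy: {e_in:.4f} -> {e_out:.4f}"
                )
    except CleaningError:
        raise
    except Exception as exc:
        raise CleaningError(f"force-field cleanup failed: {exc}") from exc

    out = np.array(mol.GetConformer().GetPositions(), dtype=float)
    for (i, j), ref in ligand.ref_bond_lengths().items():
        got = float(np.linalg.norm(out[i] - out[j]))
        if abs(got - ref) > 0.2 * ref:
            raise CleaningError(
                f"bond {i}-{j} length {got:.3f} Å deviates >20% from "
                f"reference {ref:.3f} Å after cleaning"
            )
    return out


def embed_constrained(
    ligand: LigandGraph,
    initial_coords: np.ndarray,
    ca_order: Sequence[int],
    targets: np.ndarray,
    metal: str,
    seed: int,
    delta_site: float = 0.05,
    f_metal: float = 0.8,
    **embed_kwargs,
) -> tuple[np.ndarray, float]:
    """Distance-geometry embedding of a ligand against its binding site.

    The ligand bounds matrix is extended with one extra center (the metal):
    metal-CA distances are pinned to the target bond lengths, CA-CA
    distances to the site chord separations, and every other atom keeps a
    covalent-radius floor away from the metal. The embedded geometry is
    then translated to put the metal at the origin and Kabsch-rotated so
    the CAs meet the actual targets; the rotation residual is returned as
    the rotRMSD. An infeasible site (chords the ligand backbone cannot
    span) surfaces as :class:`EmbeddingError` during bounds validation.
    """
    from .elements import covalent_radius

    targets = np.asarray(targets, dtype=float)
    base = build_bounds(ligand, initial_coords)
    n = ligand.n_atoms
    lower = np.zeros((n + 1, n + 1))
    upper = np.full((n + 1, n + 1), BOUNDS_DEFAULTS["upper_cap"])
    lower[:n, :n] = base.lower
    upper[:n, :n] = base.upper
    rc_m = covalent_radius(metal)
    for i, (el, _) in enumerate(ligand.atoms):
        lower[i, n] = lower[n, i] = f_metal * (rc_m + covalent_radius(el))
    for k, ca in enumerate(ca_order):
        L = float(np.linalg.norm(targets[k]))
        lower[ca, n] = lower[n, ca] = L - 0.02
        upper[ca, n] = upper[n, ca] = L + 0.02
    for a in range(len(ca_order)):
        for b in range(a + 1, len(ca_order)):
            chord = float(np.linalg.norm(targets[a] - targets[b]))
            i, j = ca_order[a], ca_order[b]
            lower[i, j] = lower[j, i] = chord - delta_site
            upper[i, j] = upper[j, i] = chord + delta_site
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    # re-smooth with the new constraints in place
    for k in range(n + 1):
        upper = np.minimum(upper, upper[:, k, None] + upper[None, k, :])
    for k in range(n + 1):
        lower = np.maximum(lower, lower[:, k, None] - upper[None, k, :])
        lower = np.maximum(lower, lower[None, k, :] - upper[:, k, None])
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    bounds = DistanceBounds(lower=lower, upper=upper)
    coords = embed_distance_geometry(bounds, seed, **embed_kwargs)
    coords = coords - coords[n]  # metal to origin
    lig = coords[:n]
    R, rmsd = kabsch_align(lig[list(ca_order)], targets)
    return lig @ R.T, float(rmsd)


def conform_to_sites(
    ligand: LigandGraph,
    coords: np.ndarray,
    ca_order: Sequence[int],
    targets: np.ndarray,
    max_its: int = 300,
) -> np.ndarray:
    """Force-field polish of a site-spanning ligand with its CAs pinned.

    Starting from a geometry that already spans the binding site (e.g. a
    site-constrained embedding), each coordinating atom is fixed at its
    exact target position and the rest of the ligand relaxes around them,
    absorbing chelate strain in angles and torsions. Bonds must stay within
    20% of their prepared reference lengths or the conformer is rejected
    with :class:`CleaningError`. The force field knows nothing about the
    metal, so callers should verify metal clearance afterwards and fall
    back to the unpolished geometry if the backbone drifted toward the
    origin.
    """
    coords = np.asarray(coords, dtype=float).copy()
    targets = np.asarray(targets, dtype=float)
    for k, ca in enumerate(ca_order):
        coords[ca] = targets[k]
    n_lig = ligand.n_atoms
    if n_lig == 1:
        return coords

    mol = Chem.Mol(ligand.mol)
    conf = mol.GetConformer()
    for i in range(n_lig):
        conf.SetAtomPosition(i, coords[i].tolist())
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            props = AllChem.MMFFGetMoleculeProperties(mol)
            ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        else:
            ff = AllChem.UFFGetMoleculeForceField(mol)
        if ff is None:
            raise CleaningError("force field setup failed")
        for ca in ca_order:
            ff.AddFixedPoint(int(ca))
        ff.Initialize()
        ff.Minimize(maxIts=max_its)
    except CleaningError:
        raise
    except Exception as exc:
        raise CleaningError(f"site conformation failed: {exc}") from exc

    out = np.array(mol.GetConformer().GetPositions(), dtype=float)[:n_lig]
    for (i, j), ref in ligand.ref_bond_lengths().items():
        got = float(np.linalg.norm(out[i] - out[j]))
        if abs(got - ref) > 0.2 * ref:
            raise CleaningError(
                f"bond {i}-{j} strained to {got:.3f} Å (ref {ref:.3f} Å) "
                "while conforming to sites"
            )
    return out


def kabsch_align(
    ca_coords: np.ndarray, target_sites: np.ndarray
) -> tuple[np.ndarray, float]:
    """Proper rotation about the origin minimizing CA-to-target RMSD.

    No translation: the metal sits at the origin and the ligand pivots
    around it. Returns the 3x3 rotation matrix R (apply as ``x @ R.T``) and
    the minimized RMSD in Å; det(R) = +1 always.
    """
    P = np.asarray(ca_coords, dtype=float)
    Q = np.asarray(target_sites, dtype=float)
    if P.ndim != 2 or P.shape != Q.shape or P.shape[0] < 1:
        raise ValueError("coordinate sets must match and be non-empty")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
    return R, rmsd


@dataclass
class PlacedLigand:
    """A ligand conformer rigidly placed against the core (metal at origin)."""

    coordinates: np.ndarray
    rot_rmsd: float
    source_seed: int
    ligand: LigandGraph = field(repr=False, compare=False, default=None)
    site: BindingSite = field(repr=False, compare=False, default=None)
    ca_order: tuple[int, ...] = field(compare=False, default=())
    ca_targets: np.ndarray = field(repr=False, compare=False, default=None)


def _axis_angle_rotation(axis: np.ndarray, theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = np.cos(theta), np.sin(theta)
    cc = 1 - c
    return np.array(
        [
            [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
            [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
            [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
        ]
    )


def _superpose_with_translation(P: np.ndarray, Q: np.ndarray):
    """Kabsch with translation: rigid (R, t) minimizing |P@R.T + t - Q|."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - cp @ R.T
    return R, t


def _preposition(
    coords: np.ndarray, ca_idx: Sequence[int], targets: np.ndarray
) -> np.ndarray:
    """Rigidly pre-place the ligand so its CAs sit near the targets with the
    ligand body pointing away from the metal."""
    cas = coords[list(ca_idx)]
    R, t = _superpose_with_translation(cas, targets)
    placed = coords @ R.T + t

    d = len(ca_idx)
    if d > 2 or coords.shape[0] == d:
        return placed
    # low denticity leaves a free spin about the CA set: point the body outward
    ca_centroid = placed[list(ca_idx)].mean(axis=0)
    body = placed.mean(axis=0) - ca_centroid
    if np.linalg.norm(body) < 1e-9:
        return placed
    outward = targets.mean(axis=0)
    if np.linalg.norm(outward) < 1e-9:
        return placed
    outward = outward / np.linalg.norm(outward)
    if d == 1:
        # rotate about the CA point: align body direction to outward
        w = body / np.linalg.norm(body)
        axis = np.cross(w, outward)
        if np.linalg.norm(axis) < 1e-9:
            Rb = np.eye(3) if w @ outward > 0 else -np.eye(3) + 2 * np.outer(w, w)
        else:
            theta = np.arccos(np.clip(w @ outward, -1, 1))
            Rb = _axis_angle_rotation(axis, theta)
    else:
        # rotate about the CA-CA axis: maximize body . outward
        axis = placed[ca_idx[1]] - placed[ca_idx[0]]
        axis = axis / np.linalg.norm(axis)
        w = body
        a = (w - axis * (axis @ w)) @ outward
        b = np.cross(axis, w) @ outward
        if abs(a) < 1e-12 and abs(b) < 1e-12:
            return placed
        theta = np.arctan2(b, a)
        Rb = _axis_angle_rotation(axis, theta)
    return (placed - ca_centroid) @ Rb.T + ca_centroid


def place_ligand(
    ligand: LigandGraph,
    coords: np.ndarray,
    site: BindingSite,
    core: CoreGeometry,
    m_ca_lengths: Sequence[float],
    source_seed: int = 0,
) -> PlacedLigand:
    """Rigidly place a ligand conformer onto its assigned core sites.

    Target positions are the site unit vectors scaled by the metal-CA bond
    lengths. The ligand is pre-positioned (CAs superposed onto the targets,
    body oriented away from the metal), then the final alignment is a
    rotation about the origin from :func:`kabsch_align`, whose residual is
    recorded as ``rot_rmsd``. All CA-to-site pairings (d! for denticity d)
    are tried and the lowest-rotRMSD one kept. The motion is rigid: internal
    ligand geometry is preserved exactly.
    """
    import itertools

    coords = np.asarray(coords, dtype=float)
    idx = list(site.core_site_indices)
    lengths = np.asarray(m_ca_lengths, dtype=float)
    if lengths.shape != (len(idx),):
        raise ValueError("one metal-CA length per coordinating atom required")

    best = None
    for perm in itertools.permutations(range(len(idx))):
        # CA k pairs with site idx[position]; its own bond length travels
        # with it so heteroleptic CA sets keep the right M-CA distances
        ca_order = tuple(ligand.ca_indices[k] for k in perm)
        targets = core.site_vectors[idx] * lengths[list(perm), None]
        pre = _preposition(coords, ca_order, targets)
        R, rmsd = kabsch_align(pre[list(ca_order)], targets)
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, pre @ R.T, ca_order, targets)
    rmsd, final, ca_order, targets = best
    return PlacedLigand(
        coordinates=final,
        rot_rmsd=float(rmsd),
        source_seed=int(source_seed),
        ligand=ligand,
        site=site,
        ca_order=ca_order,
        ca_targets=targets,
    )
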