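"""Pluggable energy calculators for assembly scoring and final relaxation.

The builder treats the evaluator as swappable: anything satisfying
:class:`CalculatorContract` (an ``evaluate``/``relax``/``supports`` trio)
can score candidate placements and relax assembled complexes. The package
ships :class:`ScaffoldCalculator`, a lightweight classical potential that
keeps the whole pipeline runnable and deterministic with no external
binaries:

* harmonic bond terms centered on bond-order-scaled covalent-radius sums,
* a Coulomb-like 1/d repulsion between atoms geminal through a metal center
  (the Kepert picture: coordinated atoms repel on the coordination sphere,
  so six monodentate ligands relax toward the octahedron),
* Lennard-Jones nonbonded terms (pairs three or more bonds apart) with
  minima at scaled van-der-Waals-radius sums,
* Coulomb terms on formal charges over the same nonbonded pairs,
* a constant per-atom reference energy (like the atomic self-energies of an
  electronic-structure total energy) that keeps totals negative, so the
  assembly bias energy x (1/rotRMSD) prefers well-aligned placements,
* during relaxation only, harmonic geminal (1-3) restraints — snapshotted
  from the input geometry — on pairs geminal through an *organic* center,
  preserving intra-ligand angles while bond lengths and clashes anneal.

Because the relax-only restraints are zero at the input coordinates, the
relax objective equals the single-point energy at the start, and the
minimizer makes it non-increasing — the energy-monotonicity contract is
exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.optimize import minimize

from .elements import ELEMENTS, covalent_radius, vdw_radius

__all__ = ["CalculatorContract", "ScaffoldCalculator", "COULOMB_CONSTANT"]

COULOMB_CONSTANT = 332.0637  # kcal/mol * Å / e^2

# bond-order scaling of covalent-radius-sum reference lengths
_ORDER_FACTOR = {1.0: 1.0, 1.5: 0.93, 2.0: 0.87, 3.0: 0.78}


@runtime_checkable
class CalculatorContract(Protocol):
    """Minimal evaluator interface the assembly pipeline relies on."""

    name: str

    def supports(self, element: str) -> bool: ...

    def evaluate(
        self,
        elements: Sequence[str],
        coordinates: np.ndarray,
        charge: int = 0,
        multiplicity: int = 1,
        graph: Optional[Sequence[tuple]] = None,
        formal_charges: Optional[Sequence[float]] = None,
    ) -> float: ...

    def relax(
        self,
        elements: Sequence[str],
        coordinates: np.ndarray,
        charge: int = 0,
        multiplicity: int = 1,
        graph: Optional[Sequence[tuple]] = None,
        formal_charges: Optional[Sequence[float]] = None,
        max_steps: int = 200,
    ) -> tuple[np.ndarray, float, bool]: ...


def _topological_distances(n: int, bonds: Sequence[tuple]) -> np.ndarray:
    adj: list[list[int]] = [[] for _ in range(n)]
    for b in bonds:
        i, j = int(b[0]), int(b[1])
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full((n, n), 10**6, dtype=int)
    for src in range(n):
        dist[src, src] = 0
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                du = dist[src, u]
                if du >= 3:  # only 1,2,3+ classes matter
                    continue
                for v in adj[u]:
                    if dist[src, v] > du + 1:
                        dist[src, v] = du + 1
                        nxt.append(v)
            queue = nxt
    return dist


def _is_metal(element: str) -> bool:
    rec = ELEMENTS.get(element)
    return bool(rec and rec.default_oxidation_states)


@dataclass
class _PairTerms:
    """Precompiled pair lists for one (elements, graph) system."""

    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    gem_i: np.ndarray  # geminal through an organic center (relax restraints)
    gem_j: np.ndarray
    rep_i: np.ndarray  # geminal through a metal center (Kepert repulsion)
    rep_j: np.ndarray
    nb_i: np.ndarray
    nb_j: np.ndarray
    nb_rmin: np.ndarray
    nb_qq: np.ndarray


class ScaffoldCalculator:
    """Built-in lightweight classical potential (see module docstring).

    Parameters are in kcal/mol and Å. ``charge`` and ``multiplicity`` are
    accepted for contract compatibility but do not enter the classical
    energy expression (formal charges do, via the Coulomb term).
    """

    name = "scaffold"

    def __init__(
        self,
        k_bond: float = 300.0,
        k_geminal: float = 60.0,
        lj_epsilon: float = 0.05,
        lj_rmin_scale: float = 0.8,
        coulomb_scale: float = 1.0,
        ca_repulsion: float = 50.0,  # kcal/mol * Å, Kepert 1/d term
        atom_energy: float = -100.0,  # kcal/mol per-atom reference
    ):
        self.k_bond = k_bond
        self.k_geminal = k_geminal
        self.lj_epsilon = lj_epsilon
        self.lj_rmin_scale = lj_rmin_scale
        self.coulomb_scale = coulomb_scale
        self.ca_repulsion = ca_repulsion
        self.atom_energy = atom_energy
        self._cache: dict = {}

    def supports(self, element: str) -> bool:
        return element in ELEMENTS

    # -- term compilation ---------------------------------------------------

    def _terms(
        self,
        elements: Sequence[str],
        graph: Sequence[tuple],
        formal_charges: Optional[Sequence[float]],
    ) -> _PairTerms:
        key = (
            tuple(elements),
            tuple((int(i), int(j), float(o)) for i, j, o in graph),
            tuple(formal_charges) if formal_charges is not None else None,
        )
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n = len(elements)
        rcov = np.array([covalent_radius(el) for el in elements])
        vdw = np.array([vdw_radius(el) for el in elements])
        q = (
            np.asarray(formal_charges, dtype=float)
            if formal_charges is not None
            else np.zeros(n)
        )
        topo = _topological_distances(n, graph)

        bi, bj, br0 = [], [], []
        adj: list[set] = [set() for _ in range(n)]
        for i, j, order in graph:
            f = _ORDER_FACTOR.get(float(order), 1.0)
            i, j = int(i), int(j)
            bi.append(i)
            bj.append(j)
            br0.append(f * (rcov[i] + rcov[j]))
            adj[i].add(j)
            adj[j].add(i)
        metal = np.array([_is_metal(el) for el in elements])

        gi_all, gj_all = np.where(np.triu(topo == 2, 1))
        gem_i, gem_j, rep_i, rep_j = [], [], [], []
        for i, j in zip(gi_all, gj_all):
            common = adj[i] & adj[j]
            # a pair bridged only by metal centers repels (Kepert); any
            # organic bridge means a covalent angle worth restraining
            if common and all(metal[k] for k in common):
                rep_i.append(i)
                rep_j.append(j)
            else:
                gem_i.append(i)
                gem_j.append(j)
        ni, nj = np.where(np.triu(topo >= 3, 1))
        terms = _PairTerms(
            bond_i=np.asarray(bi, dtype=int),
            bond_j=np.asarray(bj, dtype=int),
            bond_r0=np.asarray(br0),
            gem_i=np.asarray(gem_i, dtype=int),
            gem_j=np.asarray(gem_j, dtype=int),
            rep_i=np.asarray(rep_i, dtype=int),
            rep_j=np.asarray(rep_j, dtype=int),
            nb_i=ni,
            nb_j=nj,
            nb_rmin=self.lj_rmin_scale * (vdw[ni] + vdw[nj]),
            nb_qq=self.coulomb_scale * COULOMB_CONSTANT * q[ni] * q[nj],
        )
        if len(self._cache) > 256:
            self._cache.clear()
        self._cache[key] = terms
        return terms

    # -- energy / gradient --------------------------------------------------

    def _energy_grad(
        self,
        coords: np.ndarray,
        terms: _PairTerms,
        gem_r0: Optional[np.ndarray] = None,
    ) -> tuple[float, np.ndarray]:
        x = coords
        e = 0.0
        grad = np.zeros_like(x)

        def add_pairs(ii, jj, de_dd_fn, e_fn):
            nonlocal e
            if len(ii) == 0:
                return
            diff = x[ii] - x[jj]
            d = np.linalg.norm(diff, axis=1)
            d = np.maximum(d, 1e-8)
            e_pair = e_fn(d)
            de = de_dd_fn(d)
            e += float(np.sum(e_pair))
            g = (de / d)[:, None] * diff
            np.add.at(grad, ii, g)
            np.add.at(grad, jj, -g)

        r0 = terms.bond_r0
        add_pairs(
            terms.bond_i,
            terms.bond_j,
            lambda d: 2.0 * self.k_bond * (d - r0),
            lambda d: self.k_bond * (d - r0) ** 2,
        )
        if gem_r0 is not None and len(terms.gem_i):
            add_pairs(
                terms.gem_i,
                terms.gem_j,
                lambda d: 2.0 * self.k_geminal * (d - gem_r0),
                lambda d: self.k_geminal * (d - gem_r0) ** 2,
            )
        if len(terms.rep_i):
            c = self.ca_repulsion
            add_pairs(
                terms.rep_i,
                terms.rep_j,
                lambda d: -c / d**2,
                lambda d: c / d,
            )
        if len(terms.nb_i):
            rmin = terms.nb_rmin
            qq = terms.nb_qq
            eps = self.lj_epsilon

            def e_nb(d):
                s6 = (rmin / d) ** 6
                return eps * (s6 * s6 - 2.0 * s6) + qq / d

            def de_nb(d):
                s6 = (rmin / d) ** 6
                return (-12.0 * eps / d) * (s6 * s6 - s6) - qq / d**2

            add_pairs(terms.nb_i, terms.nb_j, de_nb, e_nb)
        return e, grad

    # -- contract -----------------------------------------------------------

    def evaluate(
        self,
        elements,
        coordinates,
        charge: int = 0,
        multiplicity: int = 1,
        graph=None,
        formal_charges=None,
    ) -> float:
        if graph is None:
            raise ValueError("ScaffoldCalculator requires the bond graph")
        coords = np.asarray(coordinates, dtype=float)
        terms = self._terms(elements, graph, formal_charges)
        e, _ = self._energy_grad(coords, terms)
        return e + self.atom_energy * len(elements)

    def relax(
        self,
        elements,
        coordinates,
        charge: int = 0,
        multiplicity: int = 1,
        graph=None,
        formal_charges=None,
        max_steps: int = 200,
    ) -> tuple[np.ndarray, float, bool]:
        if graph is None:
            raise ValueError("ScaffoldCalculator requires the bond graph")
        coords = np.asarray(coordinates, dtype=float)
        terms = self._terms(elements, graph, formal_charges)
        # geminal restraints snapshot the input angles; zero energy at start
        if len(terms.gem_i):
            gem_r0 = np.linalg.norm(
                coords[terms.gem_i] - coords[terms.gem_j], axis=1
            )
        else:
            gem_r0 = None

        shift = self.atom_energy * len(elements)

        def objective(flat):
            e, g = self._energy_grad(flat.reshape(coords.shape), terms, gem_r0)
            return e, g.ravel()

        e0, _ = objective(coords.ravel())
        res = minimize(
            objective,
            coords.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": int(max_steps)},
        )
        out = res.x.reshape(coords.shape)
        e_final, _ = objective(res.x)
        if e_final > e0:  # keep the monotonicity contract exact
            return coords.copy(), float(e0) + shift, False
        return out, float(e_final) + shift, bool(res.success)
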