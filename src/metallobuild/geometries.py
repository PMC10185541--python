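"""Coordination polyhedra and ligand coordination types.

Two plain-text data files back this module:

``data/core_geometries.json``
    Idealized metal-center polyhedra for CN 1-12, each a named list of unit
    vectors (metal at the origin). The roster covers the standard
    coordination-chemistry shapes (octahedral, square antiprismatic,
    tricapped trigonal prismatic, ...) and is a reconstruction of the usual
    textbook set; users can register additional shapes at run time with
    :func:`register_core_geometry`.

``data/ligand_types.json``
    Ligand coordination types defined by their CA-M-CA angle pattern
    (bidentate cis vs trans, tridentate fac vs mer, ...). A type with
    denticity d stores d*(d-1)/2 angles in degrees.

Angles are degrees at every API boundary; radians are internal only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import (
    DegenerateInputError,
    UnsupportedCNError,
    UnsupportedDenticityError,
)

__all__ = [
    "CoreGeometry",
    "LigandType",
    "list_core_geometries",
    "get_core_geometry",
    "register_core_geometry",
    "classify_ligand_type",
    "ligand_types_for",
    "angle_between_sites",
    "pairwise_site_angles",
    "match_angle_sets",
    "MIN_CN",
    "MAX_CN",
]

MIN_CN, MAX_CN = 1, 12


@dataclass(frozen=True)
class CoreGeometry:
    """A named coordination polyhedron: ``cn`` unit vectors on the sphere."""

    name: str
    cn: int
    site_vectors: np.ndarray  # (cn, 3), rows unit norm

    def __post_init__(self):
        vecs = np.asarray(self.site_vectors, dtype=float)
        if vecs.shape != (self.cn, 3):
            raise ValueError(f"{self.name}: expected ({self.cn}, 3) vectors")
        norms = np.linalg.norm(vecs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: site vectors must be unit norm")
        for i in range(self.cn):
            for j in range(i + 1, self.cn):
                if np.linalg.norm(vecs[i] - vecs[j]) < 1e-8:
                    raise ValueError(f"{self.name}: duplicate sites {i},{j}")
        object.__setattr__(self, "site_vectors", vecs)

    def pair_angles(self) -> np.ndarray:
        """Symmetric (cn, cn) matrix of inter-site angles in degrees."""
        return pairwise_site_angles(self.site_vectors)


@dataclass(frozen=True)
class LigandType:
    """A ligand coordination type, defined by its CA-M-CA angle pattern."""

    name: str
    denticity: int
    ca_angles: tuple[float, ...]  # degrees, one per CA pair

    def __post_init__(self):
        n_pairs = self.denticity * (self.denticity - 1) // 2
        if len(self.ca_angles) != n_pairs:
            raise ValueError(
                f"{self.name}: denticity {self.denticity} needs {n_pairs} "
                f"angles, got {len(self.ca_angles)}"
            )
        if any(not (0.0 < a <= 180.0) for a in self.ca_angles):
            raise ValueError(f"{self.name}: angles must lie in (0, 180]")


def _load_geometries() -> list[CoreGeometry]:
    path = resources.files("metallobuild.data") / "core_geometries.json"
    with path.open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        CoreGeometry(r["name"], int(r["cn"]), np.asarray(r["site_vectors"]))
        for r in raw
    ]


def _load_ligand_types() -> list[LigandType]:
    path = resources.files("metallobuild.data") / "ligand_types.json"
    with path.open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        LigandType(r["name"], int(r["denticity"]), tuple(r["ca_angles"]))
        for r in raw
    ]


_GEOMETRIES: list[CoreGeometry] = _load_geometries()
_LIGAND_TYPES: list[LigandType] = _load_ligand_types()


def register_core_geometry(geometry: CoreGeometry) -> None:
    """Append a user-defined polyhedron to the run-time registry."""
    if any(g.name == geometry.name for g in _GEOMETRIES):
        raise ValueError(f"geometry {geometry.name!r} already registered")
    _GEOMETRIES.append(geometry)


def list_core_geometries(cn: int) -> list[CoreGeometry]:
    """All stored polyhedra with the given coordination number, in file order."""
    if not MIN_CN <= cn <= MAX_CN:
        raise UnsupportedCNError(
            f"coordination number {cn} outside supported range "
            f"[{MIN_CN}, {MAX_CN}]"
        )
    return [g for g in _GEOMETRIES if g.cn == cn]


def get_core_geometry(name: str) -> CoreGeometry:
    for g in _GEOMETRIES:
        if g.name == name:
            return g
    raise KeyError(f"no core geometry named {name!r}")


def ligand_types_for(denticity: int) -> list[LigandType]:
    """Every stored type of the given denticity (brute-force search pool)."""
    types = [t for t in _LIGAND_TYPES if t.denticity == denticity]
    if not types:
        raise UnsupportedDenticityError(
            f"no ligand type defined for denticity {denticity}"
        )
    return types


def match_angle_sets(observed: Sequence[float], template: Sequence[float]) -> float:
    """Minimum summed |Δangle| over bipartite pairings of two angle lists.

    Used both for classifying ligand types from angle estimates and for
    matching candidate core-site combinations against a type's template;
    optimal pairing (not a sorted zip) keeps fac/mer discrimination robust.
    """
    obs = np.asarray(observed, dtype=float)
    tpl = np.asarray(template, dtype=float)
    if obs.shape != tpl.shape:
        raise ValueError("angle lists must have equal length")
    if obs.size == 0:
        return 0.0
    cost = np.abs(obs[:, None] - tpl[None, :])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def classify_ligand_type(
    denticity: int, ca_angle_estimates: Optional[Sequence[float]] = None
) -> LigandType:
    """Pick the stored ligand type closest to the observed CA-M-CA angles.

    With no estimates the first stored type of that denticity is returned
    (the table is ordered so that the most common type — cis for bidentate,
    fac for tridentate — comes first). Ties break by table order.
    """
    types = ligand_types_for(denticity)
    if ca_angle_estimates is None:
        return types[0]
    n_pairs = denticity * (denticity - 1) // 2
    if len(ca_angle_estimates) != n_pairs:
        raise ValueError(
            f"denticity {denticity} requires {n_pairs} angle estimates, "
            f"got {len(ca_angle_estimates)}"
        )
    best, best_dev = None, np.inf
    for t in types:
        dev = match_angle_sets(ca_angle_estimates, t.ca_angles)
        if dev < best_dev - 1e-12:
            best, best_dev = t, dev
    return best


def angle_between_sites(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two unit site vectors, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateInputError("zero-length site vector")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def pairwise_site_angles(vectors: np.ndarray) -> np.ndarray:
    """Symmetric matrix of angles (degrees) between rows of ``vectors``."""
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateInputError("zero-length site vector")
    unit = v / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    return np.degrees(np.arccos(cos))
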