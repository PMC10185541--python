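"""Deterministic toy complexes for exercising every pipeline stage.

Each fixture is a fully specified build request — metal, CN, ligand recipes
with coordinating atoms — small enough that exhaustive oracles (permutation
RMSD, assignment enumeration) stay feasible, plus, where it can be written
down analytically, an idealized reference structure. Nothing is downloaded;
everything is constructed in code.

Registry:

``hexaaqua_Fe``
    Fe(III) + 6 water, CN 6, with an exact octahedral reference structure.
``octahedral_mixed_Ce``
    Ce(III) + diethylenetriamine (tridentate) + ethylenediamine (bidentate)
    + water on an octahedral core: mixed denticities.
``cn8_monodentates``
    8 distinct monodentate ligands on a CN 8 La core (8! = 40,320 raw
    binding-site maps).
``cn8_water_ethanol``
    4 water + 4 ethanol on CN 8 (8-choose-4 = 70 unique maps after
    identical-ligand deduplication).
``cn9_La_tricapped``
    9 water on a CN 9 La core (tricapped-trigonal-prismatic territory).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .assembly import BuildRequest, LigandInput
from .compare import AtomSet
from .elements import covalent_radius
from .errors import MetallobuildError
from .geometries import get_core_geometry

__all__ = ["FixtureSpec", "make_fixture", "perturb", "list_fixtures"]

_WATER_OH = 0.96  # Å
_WATER_HOH = 104.5  # degrees


@dataclass
class FixtureSpec:
    name: str
    metal: str
    cn: int
    ligand_recipes: list[LigandInput]
    seed: int
    reference: Optional[AtomSet] = None

    def __post_init__(self):
        total = sum(len(r.ca_indices) * r.count for r in self.ligand_recipes)
        if total != self.cn:
            raise ValueError(
                f"{self.name}: total denticity {total} != CN {self.cn}"
            )

    def request(self) -> BuildRequest:
        return BuildRequest(
            metal=self.metal,
            ligands=list(self.ligand_recipes),
            cn=self.cn,
            seed=self.seed,
        )


def _ideal_aqua_complex(metal: str, core_name: str) -> AtomSet:
    """Analytic M(H2O)_cn structure: O on the ideal sites, waters outward."""
    core = get_core_geometry(core_name)
    r_mo = covalent_radius(metal) + covalent_radius("O")
    half = np.radians(_WATER_HOH / 2.0)
    elements = [metal]
    coords = [np.zeros(3)]
    bonds: list[tuple[int, int]] = []
    for u in core.site_vectors:
        o_idx = len(elements)
        o_pos = r_mo * u
        # deterministic in-plane axis perpendicular to the radial direction
        helper = np.array([0.0, 0.0, 1.0])
        if abs(u @ helper) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        p = np.cross(u, helper)
        p /= np.linalg.norm(p)
        elements.append("O")
        coords.append(o_pos)
        bonds.append((0, o_idx))
        for sign in (+1.0, -1.0):
            h_pos = o_pos + _WATER_OH * (np.cos(half) * u + sign * np.sin(half) * p)
            elements.append("H")
            coords.append(h_pos)
            bonds.append((o_idx, len(elements) - 1))
    return AtomSet(
        elements=elements,
        coordinates=np.array(coords),
        graph=bonds,
        metal_index=0,
    )


def _hexaaqua_fe() -> FixtureSpec:
    return FixtureSpec(
        name="hexaaqua_Fe",
        metal="Fe",
        cn=6,
        ligand_recipes=[LigandInput("O", (0,), count=6, name="water")],
        seed=20_321,
        reference=_ideal_aqua_complex("Fe", "octahedral"),
    )


def _octahedral_mixed_ce() -> FixtureSpec:
    return FixtureSpec(
        name="octahedral_mixed_Ce",
        metal="Ce",
        cn=6,
        ligand_recipes=[
            LigandInput("NCCNCCN", (0, 3, 6), count=1, name="dien"),
            LigandInput("NCCN", (0, 3), count=1, name="en"),
            LigandInput("O", (0,), count=1, name="water"),
        ],
        seed=20_322,
    )


def _cn8_monodentates() -> FixtureSpec:
    smiles = ["O", "N", "S", "OC", "NC", "SC", "OCC", "NCC"]
    return FixtureSpec(
        name="cn8_monodentates",
        metal="La",
        cn=8,
        ligand_recipes=[LigandInput(s, (0,), count=1) for s in smiles],
        seed=20_323,
    )


def _cn8_water_ethanol() -> FixtureSpec:
    return FixtureSpec(
        name="cn8_water_ethanol",
        metal="La",
        cn=8,
        ligand_recipes=[
            LigandInput("O", (0,), count=4, name="water"),
            LigandInput("OCC", (0,), count=4, name="ethanol"),
        ],
        seed=20_324,
    )


def _cn9_la_tricapped() -> FixtureSpec:
    return FixtureSpec(
        name="cn9_La_tricapped",
        metal="La",
        cn=9,
        ligand_recipes=[LigandInput("O", (0,), count=9, name="water")],
        seed=20_325,
        reference=_ideal_aqua_complex("La", "tricapped_trigonal_prismatic"),
    )


_REGISTRY: dict[str, Callable[[], FixtureSpec]] = {
    "hexaaqua_Fe": _hexaaqua_fe,
    "octahedral_mixed_Ce": _octahedral_mixed_ce,
    "cn8_monodentates": _cn8_monodentates,
    "cn8_water_ethanol": _cn8_water_ethanol,
    "cn9_La_tricapped": _cn9_la_tricapped,
}


def list_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(name: str) -> FixtureSpec:
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise MetallobuildError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        ) from None


def perturb(structure: AtomSet, sigma: float, seed: int) -> AtomSet:
    """Gaussian coordinate noise (per-axis scale ``sigma`` Å), seeded.

    For large atom counts the expected RMSD to the parent is sigma * sqrt(3).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=structure.coordinates.shape) if sigma else 0.0
    return AtomSet(
        elements=list(structure.elements),
        coordinates=structure.coordinates + noise,
        graph=None if structure.graph is None else list(structure.graph),
        metal_index=structure.metal_index,
    )
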