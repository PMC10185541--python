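"""Shared fixtures: small ligands, cores, and reference conformers."""

from __future__ import annotations

import numpy as np
import pytest

from metallobuild import (
    AtomSet,
    Conformer,
    covalent_radius,
    make_fixture,
    prepare_ligand,
)
from metallobuild.geometries import get_core_geometry


@pytest.fixture(scope="session")
def octahedron():
    return get_core_geometry("octahedral")


@pytest.fixture(scope="session")
def water():
    return prepare_ligand("O", [0])


@pytest.fixture(scope="session")
def pyridine():
    return prepare_ligand("C1=CC=NC=C1", [3])


@pytest.fixture(scope="session")
def hexaaqua_reference():
    return make_fixture("hexaaqua_Fe").reference


def atomset_to_conformer(
    atoms: AtomSet,
    metal_oxidation: int,
    n_ligand_atoms: int,
    energy: float = 0.0,
) -> Conformer:
    """Wrap an idealized M(ligand)_n AtomSet as a Conformer for sanity tests.

    Assumes the layout the fixture generator produces: metal first, then
    whole ligands of ``n_ligand_atoms`` atoms each, with the CA leading each
    ligand block and bonded to the metal.
    """
    bonds = [(i, j, 1.0) for i, j in atoms.graph]
    n = atoms.n_atoms
    ranges = [
        (start, start + n_ligand_atoms)
        for start in range(1, n, n_ligand_atoms)
    ]
    m_el = atoms.elements[0]
    ca_info = []
    for start, _ in ranges:
        target = covalent_radius(m_el) + covalent_radius(atoms.elements[start])
        ca_info.append((start, target))
    return Conformer(
        elements=list(atoms.elements),
        coordinates=np.asarray(atoms.coordinates),
        total_charge=metal_oxidation,
        spin_multiplicity=1,
        energy=energy,
        calculator="test",
        provenance={"core": "reference"},
        graph=bonds,
        formal_charges=[float(metal_oxidation)] + [0.0] * (n - 1),
        metal_index=0,
        ligand_ranges=ranges,
        ca_info=ca_info,
    )


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish proper rotation matrix from a seeded Generator."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
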