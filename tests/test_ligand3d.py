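"""Ligand preparation, distance-geometry embedding, cleaning, placement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metallobuild import (
    DistanceBounds,
    build_bounds,
    clean_geometry,
    covalent_radius,
    embed_distance_geometry,
    kabsch_align,
    place_ligand,
    prepare_ligand,
    vdw_radius,
)
from metallobuild.errors import EmbeddingError, LigandParseError
from metallobuild.ligand3d import (
    BOUNDS_DEFAULTS,
    LigandGraph,
    _violation_stats,
    embed_constrained,
)
from metallobuild.mapping import BindingSite
from tests.conftest import random_rotation


# ---------------------------------------------------------------------------
# preparation

def test_prepare_water(water):
    graph, coords = water
    assert [el for el, _ in graph.atoms] == ["O", "H", "H"]
    assert graph.ca_indices == (0,)
    assert coords.shape == (3, 3)


def test_prepare_pyridine_explicit_h_counts(pyridine):
    """Valence bookkeeping oracle: C5H5N has 6 heavy atoms + 5 hydrogens,
    and the CA index survives hydrogen addition."""
    graph, coords = pyridine
    assert graph.n_heavy == 6
    assert graph.n_atoms == 11
    assert graph.atoms[3][0] == "N"  # 0-based heavy index 3 in the SMILES
    assert sum(1 for el, _ in graph.atoms if el == "H") == 5


@pytest.mark.parametrize(
    "smiles,cas",
    [("not_smiles", [0]), ("O", [5]), ("O", [0, 0]), ("O.O", [0])],
)
def test_prepare_rejects_bad_input(smiles, cas):
    from metallobuild.errors import MetallobuildError

    with pytest.raises(MetallobuildError):
        prepare_ligand(smiles, cas)


# ---------------------------------------------------------------------------
# bounds

def test_water_bounds_bracket_initial_geometry(water):
    graph, coords = water
    b = build_bounds(graph, coords)
    d_oh = np.linalg.norm(coords[0] - coords[1])
    assert b.lower[0, 1] == pytest.approx(d_oh - BOUNDS_DEFAULTS["delta_bond"])
    assert b.upper[0, 1] == pytest.approx(d_oh + BOUNDS_DEFAULTS["delta_bond"])
    d_hh = np.linalg.norm(coords[1] - coords[2])
    assert b.lower[1, 2] == pytest.approx(d_hh - BOUNDS_DEFAULTS["delta_13"])
    assert b.upper[1, 2] == pytest.approx(d_hh + BOUNDS_DEFAULTS["delta_13"])


def test_butane_one_four_lower_bound_is_vdw_floor():
    graph, coords = prepare_ligand("CCCC", [0])
    b = build_bounds(graph, coords)
    # heavy atoms 0..3; the 1-4 C pair carries the van der Waals floor
    expected = BOUNDS_DEFAULTS["f_vdw"] * 2 * vdw_radius("C")
    assert b.lower[0, 3] == pytest.approx(expected)


def test_bounds_invariants_after_smoothing(pyridine):
    graph, coords = pyridine
    b = build_bounds(graph, coords)
    n = graph.n_atoms
    assert np.all(b.lower <= b.upper + 1e-9)
    assert np.all(np.diag(b.lower) == 0) and np.all(np.diag(b.upper) == 0)
    for i, j, k in itertools.permutations(range(n), 3):
        assert b.upper[i, k] <= b.upper[i, j] + b.upper[j, k] + 1e-9


# ---------------------------------------------------------------------------
# embedding

def _triangle_bounds(side=1.5, slack=1e-6):
    lower = np.full((3, 3), side - slack)
    upper = np.full((3, 3), side + slack)
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    return DistanceBounds(lower=lower, upper=upper)


def test_embedding_recovers_analytic_triangle():
    coords = embed_distance_geometry(_triangle_bounds(), seed=3)
    for i, j in itertools.combinations(range(3), 2):
        d = np.linalg.norm(coords[i] - coords[j])
        assert d == pytest.approx(1.5, abs=BOUNDS_DEFAULTS["eps_dg"])


def test_embedding_is_deterministic(pyridine):
    graph, coords = pyridine
    b = build_bounds(graph, coords)
    x1 = embed_distance_geometry(b, seed=99)
    x2 = embed_distance_geometry(b, seed=99)
    assert np.array_equal(x1, x2)


def test_infeasible_bounds_raise_with_worst_pair():
    lower = np.array([[0.0, 5.0], [5.0, 0.0]])
    upper = np.array([[0.0, 1.0], [1.0, 0.0]])
    with pytest.raises(EmbeddingError) as exc:
        embed_distance_geometry(DistanceBounds(lower, upper), seed=0)
    assert exc.value.worst_pair == (0, 1)


def test_embeddings_satisfy_bounds_across_seeds(water, pyridine):
    """Max bounds violation stays within eps_dg over 100 seeds."""
    for graph, coords in (water, pyridine):
        b = build_bounds(graph, coords)
        for seed in range(100):
            x = embed_distance_geometry(b, seed=seed)
            violation, _ = _violation_stats(x, b)
            assert violation <= BOUNDS_DEFAULTS["eps_dg"]


def test_constrained_embedding_spans_the_site():
    graph, coords = prepare_ligand("NCCN", [0, 3])
    r = covalent_radius("Fe") + covalent_radius("N")
    targets = np.array([[r, 0, 0], [0, r, 0]])
    lig, rmsd = embed_constrained(
        graph, coords, graph.ca_indices, targets, "Fe", seed=4
    )
    for k, ca in enumerate(graph.ca_indices):
        assert np.linalg.norm(lig[ca] - targets[k]) < 0.45
    # nothing wrapped into the metal pocket at the origin
    radii = np.linalg.norm(lig, axis=1)
    assert radii.min() > 1.0


# ---------------------------------------------------------------------------
# cleaning

def test_clean_is_near_fixed_point_on_relaxed_geometry(pyridine):
    graph, coords = pyridine
    out = clean_geometry(graph, coords)
    rmsd = np.sqrt(np.mean(np.sum((out - coords) ** 2, axis=1)))
    assert rmsd < 0.1


def test_clean_restores_stretched_bond(water):
    """Harmonic-relaxation oracle on a stretched O-H: the force field must
    return the bond to within 20% of its reference length."""
    graph, coords = water
    stretched = coords.copy()
    ref = np.linalg.norm(coords[1] - coords[0])
    stretched[1] = coords[0] + 1.5 * (coords[1] - coords[0])
    out = clean_geometry(graph, stretched)
    got = np.linalg.norm(out[1] - out[0])
    assert abs(got - ref) <= 0.2 * ref


# ---------------------------------------------------------------------------
# Kabsch alignment (rotation-only, about the metal at the origin)

def test_kabsch_identity_on_equal_sets():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(5, 3))
    R, rmsd = kabsch_align(x, x)
    np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_kabsch_recovers_known_rotation():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(4, 3))
    Q = random_rotation(rng)
    R, rmsd = kabsch_align(x, x @ Q.T)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(R, Q, atol=1e-8)
    assert np.linalg.det(R) == pytest.approx(1.0)


def _rotation_oracle(P, Q):
    """Independent optimum: numeric minimization over rotation vectors."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    def cost(v):
        R = Rotation.from_rotvec(v).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(8)
    for _ in range(12):
        res = minimize(cost, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def test_kabsch_matches_rotation_search_oracle():
    rng = np.random.default_rng(17)
    for _ in range(5):
        P = rng.normal(size=(3, 3))
        Q = rng.normal(size=(3, 3))
        _, rmsd = kabsch_align(P, Q)
        oracle = _rotation_oracle(P, Q)
        assert rmsd <= oracle + 1e-9  # Kabsch is the analytic optimum
        assert abs(rmsd - oracle) < 1e-3


@settings(max_examples=25, derandomize=True)
@given(
    arrays(np.float64, (4, 3), elements=st.floats(-5, 5, allow_nan=False))
)
def test_kabsch_self_alignment_property(x):
    R, rmsd = kabsch_align(x, x)
    assert rmsd == pytest.approx(0.0, abs=1e-7)


# ---------------------------------------------------------------------------
# placement

def test_place_monodentate_water_exact(water, octahedron):
    graph, coords = water
    r = covalent_radius("Fe") + covalent_radius("O")
    pl = place_ligand(
        graph, coords, BindingSite(0, (4,), 0.0), octahedron, [r]
    )
    assert pl.rot_rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.norm(pl.coordinates[0]) == pytest.approx(r)
    # the body points away from the metal
    assert pl.coordinates.mean(axis=0) @ octahedron.site_vectors[4] > 0


def _two_atom_ligand(separation):
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    graph = LigandGraph(
        atoms=[("N", 0), ("N", 0)],
        bonds=[(0, 1, 1.0)],
        ca_indices=(0, 1),
        smiles="synthetic",
        ref_coords=coords.copy(),
    )
    return graph, coords


def test_place_bidentate_congruent_bite_is_exact(octahedron):
    r = 2.0
    chord = r * np.sqrt(2.0)  # cis pair separation at 90 degrees
    graph, coords = _two_atom_ligand(chord)
    pl = place_ligand(graph, coords, BindingSite(0, (0, 2), 0.0), octahedron, [r, r])
    assert pl.rot_rmsd == pytest.approx(0.0, abs=1e-9)
    for k, ca in enumerate(pl.ca_order):
        assert np.linalg.norm(pl.coordinates[ca] - pl.ca_targets[k]) < 1e-8


def test_place_mismatched_bite_matches_kabsch_optimum(octahedron):
    r = 2.0
    graph, coords = _two_atom_ligand(2.2)  # shorter than the cis chord 2.83
    pl = place_ligand(graph, coords, BindingSite(0, (0, 2), 0.0), octahedron, [r, r])
    assert pl.rot_rmsd > 0.0
    oracle = _rotation_oracle(
        np.array([pl.coordinates[ca] for ca in pl.ca_order]) @ np.eye(3),
        pl.ca_targets,
    )
    # the recorded residual is already the optimum from its pre-position
    assert pl.rot_rmsd <= oracle + 1e-6


def test_placement_is_rigid(pyridine, octahedron):
    graph, coords = pyridine
    r = covalent_radius("Fe") + covalent_radius("N")
    pl = place_ligand(graph, coords, BindingSite(0, (1,), 0.0), octahedron, [r])
    d0 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    d1 = np.linalg.norm(
        pl.coordinates[:, None] - pl.coordinates[None, :], axis=-1
    )
    np.testing.assert_allclose(d0, d1, atol=1e-9)


def test_full_ligand_pipeline_determinism(pyridine):
    graph, coords = pyridine
    b = build_bounds(graph, coords)
    runs = []
    for _ in range(2):
        x = embed_distance_geometry(b, seed=1234)
        x = clean_geometry(graph, x)
        runs.append(x)
    assert np.array_equal(runs[0], runs[1])
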