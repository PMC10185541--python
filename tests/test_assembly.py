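"""Complex assembly, sanity checks, relaxation, end-to-end builds."""

import numpy as np
import pytest

from metallobuild import (
    BuildRequest,
    LigandInput,
    ScaffoldCalculator,
    assemble,
    build_complex,
    covalent_radius,
    make_fixture,
    relax,
    sanity_check,
)
from metallobuild.assembly import Conformer, SanityParams, ROT_RMSD_FLOOR
from metallobuild.elements import ElectronicState
from metallobuild.errors import (
    AssemblyInfeasibleError,
    ImpossiblePlacementError,
)
from metallobuild.geometries import get_core_geometry, pairwise_site_angles
from metallobuild.ligand3d import LigandGraph, PlacedLigand
from metallobuild.mapping import BindingAssignment, BindingSite
from tests.conftest import atomset_to_conformer

IDEAL_OCT = np.sort([90.0] * 12 + [180.0] * 3)


def ca_angle_multiset(conf: Conformer) -> np.ndarray:
    cas = [ca for ca, _ in conf.ca_info]
    vecs = conf.coordinates[cas] - conf.coordinates[conf.metal_index]
    ang = pairwise_site_angles(vecs)
    iu = np.triu_indices(len(cas), 1)
    return np.sort(ang[iu])


# ---------------------------------------------------------------------------
# sanity checks

def test_reference_hexaaqua_passes_both_stages(hexaaqua_reference):
    conf = atomset_to_conformer(hexaaqua_reference, metal_oxidation=3,
                                n_ligand_atoms=3)
    for stage in ("pre_eval", "post_relax"):
        ok, reason = sanity_check(conf, stage)
        assert ok, f"{stage}: {reason}"


def test_close_nonbonded_pair_fails(hexaaqua_reference):
    conf = atomset_to_conformer(hexaaqua_reference, 3, 3)
    coords = conf.coordinates.copy()
    # drag one distal H onto another ligand's O: non-bonded contact
    coords[2] = coords[4] + np.array([0.3, 0.0, 0.0])
    conf.coordinates = coords
    ok, reason = sanity_check(conf, "pre_eval")
    assert not ok and reason in ("inter_ligand_clash", "nonbonded_contact")


def test_detached_ca_fails_window_and_graph_fidelity(hexaaqua_reference):
    conf = atomset_to_conformer(hexaaqua_reference, 3, 3)
    coords = conf.coordinates.copy()
    start = conf.ligand_ranges[0][0]
    coords[start:start + 3] = coords[start:start + 3] * 2.0  # detach one water
    conf.coordinates = coords
    ok, reason = sanity_check(conf, "pre_eval")
    assert not ok and reason == "ca_displaced"
    ok, reason = sanity_check(conf, "post_relax")
    assert not ok


# ---------------------------------------------------------------------------
# greedy assembly against a scripted calculator

class ScriptedCalculator:
    """Deterministic mock: energy is a linear functional of the coordinates,
    so an independent oracle can score candidates analytically."""

    name = "scripted"

    def supports(self, element):
        return True

    def evaluate(self, elements, coordinates, charge=0, multiplicity=1,
                 graph=None, formal_charges=None):
        return -1000.0 + float(np.sum(np.asarray(coordinates)[:, 0]))

    def relax(self, elements, coordinates, charge=0, multiplicity=1,
              graph=None, formal_charges=None, max_steps=200):
        return np.asarray(coordinates), self.evaluate(elements, coordinates), True


def _mono_graph(tag: str):
    coords = np.zeros((1, 3))
    return LigandGraph(atoms=[("N", 0)], bonds=[], ca_indices=(0,),
                       smiles=tag, ref_coords=coords)


def _placed(graph, site, core, r, rot_rmsd, x_offset):
    u = core.site_vectors[site.core_site_indices[0]]
    coords = (r * u)[None, :] + np.array([[x_offset, 0.0, 0.0]]) * 0.0
    coords = coords + np.array([[x_offset, 0, 0]]) * 1e-3  # tiny x signature
    return PlacedLigand(
        coordinates=coords, rot_rmsd=rot_rmsd, source_seed=int(x_offset),
        ligand=graph, site=site, ca_order=(0,),
        ca_targets=(r * u)[None, :],
    )


def test_greedy_selection_matches_scripted_oracle(octahedron):
    """Three monodentate ligands, several candidates each, scripted energies:
    the assembled choice sequence must equal an independent greedy replay."""
    r = 2.0
    calc = ScriptedCalculator()
    state = ElectronicState(metal_oxidation=2, total_charge=2, spin_multiplicity=1)
    sites = [BindingSite(i, (i,), 0.0) for i in range(3)]
    assignment = BindingAssignment(octahedron, tuple(sites), 0.0)
    graphs = [_mono_graph(f"L{i}") for i in range(3)]
    candidates = [
        [_placed(graphs[i], sites[i], octahedron, r, rot, off)
         for rot, off in [(0.02, 1), (0.5, 2), (1.0, 3)]]
        for i in range(3)
    ]
    conf = assemble(assignment, candidates, calc, "Fe", state)

    # independent greedy oracle over the same scripted scores
    chosen_seeds = []
    partial_x = 0.0  # metal at origin contributes 0
    for i in range(3):
        best = None
        for pl in candidates[i]:
            e = -1000.0 + partial_x + float(np.sum(pl.coordinates[:, 0]))
            score = e / max(pl.rot_rmsd, ROT_RMSD_FLOOR)
            if best is None or score < best[0]:
                best = (score, pl)
        chosen_seeds.append(best[1].source_seed)
        partial_x += float(np.sum(best[1].coordinates[:, 0]))
    assert conf.provenance["seeds"] == chosen_seeds


def test_clashing_candidate_is_rejected_before_scoring(octahedron):
    r = 2.0
    calc = ScriptedCalculator()
    state = ElectronicState(2, 2, 1)
    sites = [BindingSite(0, (0,), 0.0), BindingSite(1, (2,), 0.0)]
    assignment = BindingAssignment(octahedron, tuple(sites), 0.0)
    g0, g1 = _mono_graph("A"), _mono_graph("B")
    first = [_placed(g0, sites[0], octahedron, r, 0.02, 1)]
    # candidate 1 sits on top of ligand 0 (clash); candidate 2 is clean but
    # has a much worse (higher) score — it must still win
    clash = PlacedLigand(
        coordinates=first[0].coordinates.copy(), rot_rmsd=0.01, source_seed=9,
        ligand=g1, site=sites[1], ca_order=(0,),
        ca_targets=(r * octahedron.site_vectors[2])[None, :],
    )
    clean = _placed(g1, sites[1], octahedron, r, 5.0, 2)
    conf = assemble(assignment, [first, [clash, clean]], calc, "Fe", state)
    assert conf.provenance["seeds"][1] == 2


def test_all_candidates_failing_raises_with_ligand_index(octahedron):
    r = 2.0
    state = ElectronicState(2, 2, 1)
    sites = [BindingSite(0, (0,), 0.0), BindingSite(1, (2,), 0.0)]
    assignment = BindingAssignment(octahedron, tuple(sites), 0.0)
    g0, g1 = _mono_graph("A"), _mono_graph("B")
    first = [_placed(g0, sites[0], octahedron, r, 0.02, 1)]
    clash = PlacedLigand(
        coordinates=first[0].coordinates.copy(), rot_rmsd=0.01, source_seed=9,
        ligand=g1, site=sites[1], ca_order=(0,),
        ca_targets=(r * octahedron.site_vectors[2])[None, :],
    )
    with pytest.raises(AssemblyInfeasibleError) as exc:
        assemble(assignment, [first, [clash]], ScriptedCalculator(), "Fe", state)
    assert exc.value.ligand_index == 1


# ---------------------------------------------------------------------------
# relaxation

def test_relax_is_near_fixed_point_at_minimum(hexaaqua_reference):
    calc = ScaffoldCalculator()
    conf = atomset_to_conformer(hexaaqua_reference, 3, 3)
    once = relax(conf, calc)
    twice = relax(once, calc)
    assert twice.energy <= once.energy + 1e-9
    rmsd = np.sqrt(np.mean(np.sum((twice.coordinates - once.coordinates) ** 2,
                                  axis=1)))
    assert rmsd < 0.05


def test_relax_energy_monotonic(hexaaqua_reference):
    calc = ScaffoldCalculator()
    conf = atomset_to_conformer(hexaaqua_reference, 3, 3)
    rng = np.random.default_rng(1)
    conf.coordinates = conf.coordinates + rng.normal(scale=0.05,
                                                     size=conf.coordinates.shape)
    e_single = calc.evaluate(conf.elements, conf.coordinates,
                             graph=conf.graph,
                             formal_charges=conf.formal_charges)
    out = relax(conf, calc)
    assert out.energy <= e_single + 1e-9
    assert out.provenance["core"] == conf.provenance["core"]  # provenance kept


# ---------------------------------------------------------------------------
# build_complex end-to-end

def test_hexaaqua_build_recovers_octahedral_angles():
    res = build_complex(make_fixture("hexaaqua_Fe").request())
    best = res.conformers[0]
    assert best.sane
    assert np.all(np.abs(ca_angle_multiset(best) - IDEAL_OCT) < 10.0)
    # provenance records the *starting* symmetry, one of the CN=6 cores
    assert best.provenance["core"] in ("octahedral", "trigonal_prismatic")


def test_octahedral_recovery_from_every_cn6_start():
    """Both CN=6 starting symmetries relax into the octahedron under the
    scaffold potential (the prism collapses onto the octahedral duplicate)."""
    res = build_complex(make_fixture("hexaaqua_Fe").request())
    # both assemblies survive relaxation; the dedup keeps one representative
    assert res.report.counts["assembled"] == 2
    assert res.report.counts["survivors"] + res.report.counts[
        "duplicates_removed"] == 2
    for conf in res.conformers:
        assert np.all(np.abs(ca_angle_multiset(conf) - IDEAL_OCT) < 10.0)


def test_energies_ranked_ascending_and_duplicates_separated():
    res = build_complex(make_fixture("cn8_water_ethanol").request())
    energies = [c.energy for c in res.conformers]
    assert energies == sorted(energies)
    from metallobuild import km_rmsd
    from metallobuild.compare import AtomSet

    for i in range(min(3, len(res.conformers))):
        for j in range(i + 1, min(3, len(res.conformers))):
            a = AtomSet(res.conformers[i].elements, res.conformers[i].coordinates)
            b = AtomSet(res.conformers[j].elements, res.conformers[j].coordinates)
            assert km_rmsd(a, b) >= 0.5


def test_denticity_sum_exceeding_cn_fails_before_3d():
    request = BuildRequest(
        metal="Fe",
        ligands=[LigandInput("O", (0,), count=6)],
        cn=2,
    )
    with pytest.raises(ImpossiblePlacementError):
        build_complex(request)


def test_attrition_accounting_balances():
    for name in ("hexaaqua_Fe", "octahedral_mixed_Ce"):
        res = build_complex(make_fixture(name).request())
        assert res.report.balanced()
        c = res.report.counts
        assert c["assembled"] == (
            c.get("survivors", 0)
            + c.get("skipped_relaxation", 0)
            + c.get("pre_eval_failed", 0)
            + c.get("relaxation_failed", 0)
            + c.get("post_relax_failed", 0)
            + c.get("duplicates_removed", 0)
        )


def test_build_determinism_bitwise():
    req = make_fixture("hexaaqua_Fe").request()
    res1 = build_complex(req)
    res2 = build_complex(req)
    assert [c.energy for c in res1.conformers] == [c.energy for c in res2.conformers]
    for a, b in zip(res1.conformers, res2.conformers):
        assert np.array_equal(a.coordinates, b.coordinates)


def test_calculator_swap_changes_energies_not_bookkeeping():
    """Any CalculatorContract-conforming evaluator may replace the default;
    structural bookkeeping (counts, provenance shape) must not change."""
    req = make_fixture("hexaaqua_Fe").request()
    res_default = build_complex(req)
    shifted = ScaffoldCalculator(atom_energy=-250.0)
    res_shifted = build_complex(req, calculator=shifted)
    assert res_shifted.report.counts == {
        **res_default.report.counts,
    }
    assert len(res_shifted.conformers) == len(res_default.conformers)
    assert res_shifted.conformers[0].energy != res_default.conformers[0].energy
    assert (
        res_shifted.conformers[0].provenance["core"]
        == res_default.conformers[0].provenance["core"]
    )


def test_return_assembled_exposes_prerelaxation_complexes():
    res = build_complex(make_fixture("hexaaqua_Fe").request(),
                        return_assembled=True)
    assert res.assembled is not None and len(res.assembled) == 2
    cores = {c.provenance["core"] for c in res.assembled}
    assert cores == {"octahedral", "trigonal_prismatic"}
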