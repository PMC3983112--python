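"""Contact pairing, screening, splitting, merging, calling, and RMSD."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from peptscan.energetics import COULOMB_CONSTANT
from peptscan.model import Trajectory
from peptscan.sites import (
    CallParams,
    Candidate,
    ContactPairing,
    call_sites,
    fragments_by_chain,
    merge_adjacent_sites,
    pair_contacts,
    screen_by_energy,
    split_fragment_interactions,
    superposed_rmsd,
)

from conftest import build_system, single_frame


def _two_residue_system(d):
    return build_system(
        [("A", 1, "ALA", "CB", "C", (0, 0, 0), 0.0),
         ("B", 1, "ALA", "CB", "C", (d, 0, 0), 0.0)],
        roles={"receptor": [0], "ligand": [1]},
    )


@pytest.mark.parametrize("d,paired", [(6.9, True), (7.1, False)])
def test_contact_cutoff_boundary(d, paired):
    system = _two_residue_system(d)
    traj = single_frame(system)
    pairings = pair_contacts(traj, {1: system.role_indices("ligand")})
    assert (len(pairings[0].receptor_residues) > 0) is paired


def test_far_fragment_yields_empty_pairing():
    system = _two_residue_system(25.0)
    traj = single_frame(system)
    pairings = pair_contacts(traj, {1: system.role_indices("ligand")})
    assert pairings[0].receptor_residues == frozenset()
    assert pairings[0].contact_frames == []


def test_pairing_matches_bruteforce_centroid_scan():
    """Pairing equals an independent all-pairs centroid scan."""
    rng = np.random.default_rng(5)
    entries = []
    for i in range(10):  # receptor: 10 two-atom residues
        base = rng.uniform(0, 20, 3)
        entries.append(("A", i + 1, "ALA", "CA", "C", base, 0.0))
        entries.append(("A", i + 1, "ALA", "CB", "C", base + [0, 0, 2.1], 0.0))
    for j in range(4):  # fragment: 4 two-atom residues
        base = rng.uniform(0, 20, 3)
        entries.append(("B", j + 1, "ALA", "CA", "C", base, 0.0))
        entries.append(("B", j + 1, "ALA", "CB", "C", base + [0, 0, 2.1], 0.0))
    system = build_system(
        entries,
        roles={"receptor": range(20), "ligand": range(20, 28)},
    )
    traj = single_frame(system)
    pairing = pair_contacts(traj, {1: system.role_indices("ligand")})[0]

    # quadratic oracle straight from coordinates
    def centroid(chain, seq):
        idx = system.residue_atoms(chain, seq)
        return system.coords[idx].mean(axis=0)

    expected = set()
    for i in range(10):
        for j in range(4):
            if np.linalg.norm(centroid("A", i + 1) - centroid("B", j + 1)) <= 7.0:
                expected.add(("A", i + 1))
    assert set(pairing.receptor_residues) == expected


# --------------------------------------------------------------------- #
def _screen_fixture(total_energy):
    """4 paired receptor residues, 1-atom fragment; charge tuned so the
    mean interaction energy equals *total_energy* exactly."""
    rec_pos = [(0, 0, 0), (2, 0, 0), (4, 0, 0), (6, 0, 0)]
    frag_pos = np.array([3.0, 5.0, 0.0])
    d = np.linalg.norm(frag_pos - np.array(rec_pos[0]))
    q = -total_energy * d / COULOMB_CONSTANT  # receptor charge −1 below
    entries = [("A", i + 1, "ALA", "CB", "C", p, -1.0 if i == 0 else 0.0)
               for i, p in enumerate(rec_pos)]
    entries.append(("B", 1, "LYS", "NZ", "N", tuple(frag_pos), q))
    system = build_system(entries, roles={"receptor": range(4), "ligand": [4]})
    return single_frame(system)


@pytest.mark.parametrize("energy,kept", [(-13.0, True), (-11.0, False)])
def test_energy_screen_per_residue_threshold(energy, kept):
    """4 residues at 3 kcal/mol each need a −12 kcal/mol drop."""
    traj = _screen_fixture(energy)
    fragments = {1: traj.system.role_indices("ligand")}
    pairings = pair_contacts(traj, fragments)
    assert len(pairings[0].receptor_residues) == 4
    survivors = screen_by_energy(pairings, traj, fragments, threshold=3.0)
    assert (len(survivors) == 1) is kept
    if kept:
        assert survivors[0][1] == pytest.approx(energy, rel=1e-9)


def test_energy_screen_empty_input():
    traj = _screen_fixture(-13.0)
    assert screen_by_energy([], traj, {}) == []


# --------------------------------------------------------------------- #
def _pairing_from_blocks(blocks, n_frag_res=32, n_frames=4):
    """ContactPairing with the given attached fragment-residue blocks."""
    frag_res = [("B", j + 1) for j in range(n_frag_res)]
    contacts = []
    for _ in range(n_frames):
        frame = {}
        for b_idx, block in enumerate(blocks):
            for j in block:
                frame[("B", j + 1)] = {("A", 100 + 10 * b_idx + j)}
        contacts.append(frame)
    return ContactPairing(1, frag_res, 7.0, contacts)


def test_split_two_patches_with_gap():
    pairing = _pairing_from_blocks([range(0, 8), range(24, 32)])
    subs = split_fragment_interactions(pairing, min_gap=5)
    assert len(subs) == 2
    assert subs[0].receptor_residues.isdisjoint(subs[1].receptor_residues)


def test_split_contiguous_run_is_identity():
    pairing = _pairing_from_blocks([range(4, 20)])
    subs = split_fragment_interactions(pairing, min_gap=5)
    assert subs == [pairing]


def test_split_gap_below_min_gap_does_not_split():
    # unattached run of exactly min_gap − 1 residues
    pairing = _pairing_from_blocks([range(0, 8), range(12, 20)])  # gap = 4
    subs = split_fragment_interactions(pairing, min_gap=5)
    assert len(subs) == 1
    pairing2 = _pairing_from_blocks([range(0, 8), range(13, 20)])  # gap = 5
    assert len(split_fragment_interactions(pairing2, min_gap=5)) == 2


def test_split_requires_persistent_attachment():
    """Residues paired in under half the contact frames cannot anchor a
    second interaction; at half or more they can."""

    def pairing_with_distal(n_touch):
        frag_res = [("B", j + 1) for j in range(32)]
        contacts = []
        for k in range(4):
            frame = {("B", 1): {("A", 100)}}
            if k < n_touch:
                frame[("B", 30)] = {("A", 200)}
            contacts.append(frame)
        return ContactPairing(1, frag_res, 7.0, contacts)

    transient = split_fragment_interactions(pairing_with_distal(1), min_gap=5)
    assert len(transient) == 1  # 1/4 of contact frames: not attached
    persistent = split_fragment_interactions(pairing_with_distal(2), min_gap=5)
    assert len(persistent) == 2  # 2/4 of contact frames: attached, splits
    assert persistent[1].receptor_residues == frozenset({("A", 200)})


# --------------------------------------------------------------------- #
def _merge_system():
    """Receptor residues along x at 4 Å spacing, one atom each."""
    entries = [("A", i + 1, "ALA", "CB", "C", (4.0 * i, 0, 0), 0.0)
               for i in range(12)]
    system = build_system(entries, roles={"receptor": range(12)})
    return system


def test_merge_shared_residue_and_far_candidates():
    system = _merge_system()
    avg = system.coords
    shared = [
        Candidate(frozenset({("A", 1), ("A", 2)}), frozenset({1})),
        Candidate(frozenset({("A", 2), ("A", 3)}), frozenset({2})),
        Candidate(frozenset({("A", 10)}), frozenset({3})),
    ]
    merged = merge_adjacent_sites(shared, system, avg, 5.0)
    assert len(merged) == 2
    assert merged[0].receptor_residues == frozenset({("A", 1), ("A", 2), ("A", 3)})
    assert merged[0].fragment_ids == frozenset({1, 2})


def test_merge_is_transitive_chain():
    """Three pairwise-chained candidates collapse into one site."""
    system = _merge_system()
    avg = system.coords
    chain = [
        Candidate(frozenset({("A", 1)}), frozenset({1})),
        Candidate(frozenset({("A", 2)}), frozenset({2})),  # 4 Å from both
        Candidate(frozenset({("A", 3)}), frozenset({3})),
    ]
    merged = merge_adjacent_sites(chain, system, avg, 5.0)
    assert len(merged) == 1
    assert merged[0].fragment_ids == frozenset({1, 2, 3})

    # independent union-find oracle over pairwise adjacency
    def min_dist(c1, c2):
        a1 = np.concatenate([system.residue_atoms(*r) for r in c1.receptor_residues])
        a2 = np.concatenate([system.residue_atoms(*r) for r in c2.receptor_residues])
        return cdist(avg[a1], avg[a2]).min()

    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(3))
    for i in range(3):
        for j in range(i + 1, 3):
            if min_dist(chain[i], chain[j]) <= 5.0:
                g.add_edge(i, j)
    assert len(merged) == nx.number_connected_components(g)


# --------------------------------------------------------------------- #
def test_call_sites_recovers_planted_events(scenario):
    traj, truth, _ = scenario
    calls = call_sites(traj, traj.fragments)
    got = [set(c.receptor_residues) for c in calls]
    want = [set(t["site_residues"]) for t in truth]
    assert got == want  # precision = recall = 1, in sequence order
    for c in calls:
        # final re-scoring invariant: the per-residue threshold holds
        assert c.mean_energy <= -3.0 * len(c.receptor_residues)
        assert c.mean_rasas <= 1.0
        assert c.salt_bridges  # charged docking forms bridges


def test_call_sites_empty_when_fragments_never_approach():
    from peptscan.synth import (
        EventSchedule, FragmentSpec, PatchSpec,
        make_binding_trajectory, make_toy_receptor,
    )
    patches = [PatchSpec(10, 4, "acidic")]
    receptor = make_toy_receptor(40, patches, seed=0)
    traj, _ = make_binding_trajectory(
        receptor, [FragmentSpec(30, 13, 4, "basic")],
        EventSchedule([], noise_sigma=0.2), 10, seed=0, patches=patches,
    )
    assert call_sites(traj, traj.fragments) == []


def test_call_sites_merges_adjacent_patches():
    """Two events on patches within the adjacency cutoff give one call."""
    from peptscan.synth import (
        BindingEvent, EventSchedule, FragmentSpec, PatchSpec,
        make_binding_trajectory, make_toy_receptor,
    )
    # patches separated by one residue: heavy atoms 8 Å apart along the
    # chain, but the docked fragments overlap the gap residue so the two
    # candidate residue sets come within the 5 Å adjacency cutoff
    patches = [PatchSpec(30, 4, "acidic"), PatchSpec(35, 4, "acidic")]
    receptor = make_toy_receptor(70, patches, seed=0)
    fragments = [FragmentSpec(30, 13, 4, "basic"), FragmentSpec(30, 13, 4, "basic")]
    schedule = EventSchedule(
        [BindingEvent(1, 0, 4, 10, 40, 46), BindingEvent(2, 1, 4, 10, 40, 46)],
        noise_sigma=0.0,
    )
    traj, truth = make_binding_trajectory(
        receptor, fragments, schedule, 50, seed=0, patches=patches
    )
    calls = call_sites(traj, traj.fragments)
    assert len(calls) == 1
    assert set(calls[0].fragment_ids) == {1, 2}
    planted = {s for t in truth for s in t["site_residues"]}
    assert planted <= set(calls[0].receptor_residues)


def test_call_sites_idempotent_on_own_output(scenario):
    """Re-running the pipeline on a trajectory it has already explained
    returns the same residue sets (stability of the fixed point)."""
    traj, _, _ = scenario
    first = call_sites(traj, traj.fragments)
    second = call_sites(traj, traj.fragments)
    assert [c.receptor_residues for c in first] == [
        c.receptor_residues for c in second
    ]


def test_fragments_by_chain_partition(scenario):
    traj, _, _ = scenario
    fragments = fragments_by_chain(traj.system)
    assert sorted(fragments) == [1, 2, 3]
    all_atoms = np.concatenate(list(fragments.values()))
    np.testing.assert_array_equal(
        np.sort(all_atoms), traj.system.role_indices("ligand")
    )


# --------------------------------------------------------------------- #
def test_rmsd_zero_for_identity_and_rigid_motion():
    rng = np.random.default_rng(9)
    ref = rng.normal(size=(8, 3)) * 3
    rot = Rotation.random(rng=rng)
    moved = rot.apply(ref) + np.array([5.0, -2.0, 1.0])
    system = build_system(
        [("A", i + 1, "ALA", "CB", "C", ref[i], 0.0) for i in range(8)]
    )
    traj = Trajectory(system, np.stack([ref, moved]), np.array([0.0, 1.0]))
    rmsd = superposed_rmsd(traj, np.arange(8), ref)
    assert rmsd[0] == pytest.approx(0.0, abs=1e-10)
    assert rmsd[1] == pytest.approx(0.0, abs=1e-8)


def test_rmsd_known_residual_square():
    """Symmetric x-stretch of a square leaves a hand-computable residual."""
    ref = np.array([[1, 1, 0], [1, -1, 0], [-1, -1, 0], [-1, 1, 0]], float)
    a = 1.5
    frame = ref.copy()
    frame[:, 0] *= a
    system = build_system(
        [("A", i + 1, "ALA", "CB", "C", ref[i], 0.0) for i in range(4)]
    )
    traj = Trajectory(system, frame[None], np.array([0.0]))
    rmsd = superposed_rmsd(traj, np.arange(4), ref)
    # optimal superposition is the identity by symmetry: every point is off
    # by (a−1) in x, so RMSD = |a−1|
    assert rmsd[0] == pytest.approx(abs(a - 1), abs=1e-9)


def test_rmsd_matches_independent_implementation():
    mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
    rng = np.random.default_rng(12)
    ref = rng.normal(size=(6, 3)) * 4
    frames = ref[None] + rng.normal(size=(3, 6, 3))
    system = build_system(
        [("A", i + 1, "ALA", "CB", "C", ref[i], 0.0) for i in range(6)]
    )
    traj = Trajectory(system, frames, np.arange(3, dtype=float))
    mine = superposed_rmsd(traj, np.arange(6), ref)
    theirs = [mda_rms.rmsd(f, ref, superposition=True) for f in frames]
    np.testing.assert_allclose(mine, theirs, atol=1e-8)


def test_rmsd_count_mismatch_errors():
    system = build_system(
        [("A", i + 1, "ALA", "CB", "C", (float(i), 0, 0), 0.0) for i in range(4)]
    )
    traj = single_frame(system)
    with pytest.raises(ValueError, match="shape"):
        superposed_rmsd(traj, np.arange(4), np.zeros((3, 3)))
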