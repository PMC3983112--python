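"""Sphere-point SASA, RASAS, and surface-coverage behavior."""

import numpy as np
import pytest

from peptscan.model import SiteDefinition, SiteResidue, Trajectory
from peptscan.sasa import (
    fibonacci_sphere,
    rasas_series,
    sasa,
    surface_coverage,
)

from conftest import build_system, single_frame


def _lone_atom(radius=1.7):
    coords = np.array([[0.0, 0.0, 0.0]])
    radii = np.array([radius])
    return coords, radii


@pytest.mark.parametrize("n_points", [200, 960, 5000])
def test_isolated_atom_matches_closed_form(n_points):
    """Isolated-sphere SASA converges to 4π(r+p)² within 3/sqrt(n)."""
    coords, radii = _lone_atom()
    area = sasa(coords, radii, np.array([0]), np.array([], dtype=int),
                probe_radius=1.4, n_points=n_points)
    exact = 4 * np.pi * (1.7 + 1.4) ** 2
    assert abs(area[0] - exact) / exact <= 3 / np.sqrt(n_points)


def test_n_points_floor_enforced():
    coords, radii = _lone_atom()
    with pytest.raises(ValueError, match="n_points"):
        sasa(coords, radii, np.array([0]), np.array([], dtype=int), 1.4, 99)


def test_unparameterized_radius_errors():
    coords = np.array([[0.0, 0.0, 0.0]])
    radii = np.array([np.nan])
    with pytest.raises(ValueError, match="unparameterized"):
        sasa(coords, radii, np.array([0]), np.array([], dtype=int))


def test_coincident_identical_atoms_total_one_sphere():
    """Duplicated atoms resolve deterministically: one full, one empty sphere."""
    coords = np.zeros((2, 3))
    radii = np.array([1.7, 1.7])
    areas = sasa(coords, radii, np.array([0, 1]), np.array([], dtype=int), 1.4, 960)
    exact = 4 * np.pi * 3.1 ** 2
    assert areas[0] == pytest.approx(exact)
    assert areas[1] == 0.0
    assert areas.sum() == pytest.approx(exact)


def test_context_occlusion_is_monotone():
    """Adding a context atom never increases any target atom's area."""
    rng = np.random.default_rng(42)
    for _ in range(15):
        n = 6
        coords = rng.uniform(-4, 4, size=(n + 1, 3))
        radii = rng.uniform(1.2, 2.0, size=n + 1)
        target = np.arange(n)
        base = sasa(coords, radii, target, np.array([], dtype=int), 1.4, 400)
        extra = sasa(coords, radii, target, np.array([n]), 1.4, 400)
        assert np.all(extra <= base + 1e-12)


def test_occluded_fraction_matches_independent_point_count():
    """Pairwise occlusion equals a brute-force check of the same point set."""
    coords = np.array([[0.0, 0.0, 0.0], [3.0, 1.0, -0.5]])
    radii = np.array([1.7, 1.5])
    probe = 1.4
    n_points = 960
    area = sasa(coords, radii, np.array([0]), np.array([1]), probe, n_points)
    pts = coords[0] + (radii[0] + probe) * fibonacci_sphere(n_points)
    occluded = np.linalg.norm(pts - coords[1], axis=1) < radii[1] + probe
    expected = 4 * np.pi * (radii[0] + probe) ** 2 * (1 - occluded.mean())
    assert area[0] == pytest.approx(expected, rel=1e-12)


def test_sasa_cross_checked_against_independent_implementation():
    """Random clusters agree with an independent Shrake-Rupley code."""
    biotite_struc = pytest.importorskip("biotite.structure")
    rng = np.random.default_rng(7)
    coords = rng.uniform(-5, 5, size=(12, 3))
    radii = np.full(12, 1.7)
    mine = sasa(coords, radii, np.arange(12), np.array([], dtype=int), 1.4, 5000)
    arr = biotite_struc.AtomArray(12)
    arr.coord = coords
    arr.element = np.array(["C"] * 12)
    arr.res_id = np.arange(1, 13)
    arr.res_name = np.array(["LIG"] * 12)
    arr.atom_name = np.array([f"C{i}" for i in range(12)])
    theirs = biotite_struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                                point_number=5000)
    np.testing.assert_allclose(mine.sum(), theirs.sum(), rtol=0.02)


# --------------------------------------------------------------------- #
def _one_residue_site(seqs, name="ASP"):
    return SiteDefinition(1, "A", [SiteResidue(s, name) for s in seqs])


def test_rasas_is_one_without_ligand(scenario_noise_free):
    traj, truth, patches = scenario_noise_free
    receptor_only = traj.system  # ligand role present but we pass an empty role
    site = _one_residue_site([11, 12, 13, 14])
    series = rasas_series(traj, site, ligand_role="no_such_role")
    np.testing.assert_array_equal(series.ratio, 1.0)


def test_rasas_distant_ligand_is_one():
    """A ligand beyond the 2·probe proximity leaves RASAS at exactly 1."""
    system = build_system(
        [("A", 1, "ALA", "CB", "C", (0, 0, 0), 0.0),
         ("B", 1, "ALA", "CB", "C", (0, 0, 1.7 + 1.7 + 2.9), 0.0)],
        roles={"receptor": [0], "ligand": [1]},
    )
    traj = single_frame(system)
    site = SiteDefinition(1, "A", [SiteResidue(1, "ALA")])
    series = rasas_series(traj, site)
    assert series.ratio[0] == 1.0


def test_rasas_proximity_threshold_randomized():
    """RASAS < 1 iff a ligand atom is within r_s + r_l + 2·probe of a site
    atom (up to point-sampling margin near the boundary)."""
    rng = np.random.default_rng(11)
    probe = 1.4
    for _ in range(20):
        r_s = rng.uniform(1.3, 1.9)
        r_l = rng.uniform(1.3, 1.9)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        threshold = r_s + r_l + 2 * probe
        offset = rng.uniform(-0.4, 0.4)
        d = threshold + offset
        coords = np.array([np.zeros(3), d * direction])
        radii = np.array([r_s, r_l])
        area = sasa(coords, radii, np.array([0]), np.array([1]), probe, 960)
        full = 4 * np.pi * (r_s + probe) ** 2
        if offset >= 0:
            assert area[0] == pytest.approx(full, rel=1e-12)
        elif offset <= -0.05:
            assert area[0] < full - 1e-9


def test_rasas_drops_exactly_on_dwell_frames(scenario_noise_free):
    traj, truth, patches = scenario_noise_free
    ev = truth[0]
    site = _one_residue_site([s for _, s in ev["site_residues"]])
    series = rasas_series(traj, site)
    below = set(np.nonzero(series.ratio < 1 - 1e-12)[0].tolist())
    assert below == set(range(ev["dwell_start"], ev["dwell_end"] + 1))
    assert np.all(series.ratio <= 1.0)


def test_rasas_sidechain_only_requires_sidechains():
    system = build_system(
        [("A", 1, "ALA", "CA", "C", (0, 0, 0), 0.0),
         ("B", 1, "ALA", "CB", "C", (10, 0, 0), 0.0)],
        roles={"receptor": [0], "ligand": [1]},
    )
    traj = single_frame(system)
    site = SiteDefinition(1, "A", [SiteResidue(1, "ALA")])
    with pytest.raises(ValueError, match="side-chain"):
        rasas_series(traj, site, sidechain_only=True)


def test_glycine_keeps_ca_as_pseudo_sidechain():
    system = build_system(
        [("A", 1, "GLY", "CA", "C", (0, 0, 0), 0.0),
         ("B", 1, "ALA", "CB", "C", (10, 0, 0), 0.0)],
        roles={"receptor": [0], "ligand": [1]},
    )
    traj = single_frame(system)
    site = SiteDefinition(1, "A", [SiteResidue(1, "GLY")])
    series = rasas_series(traj, site, sidechain_only=True)
    assert series.ratio[0] == 1.0


# --------------------------------------------------------------------- #
def test_coverage_zero_when_fragments_far(scenario_noise_free):
    traj, truth, _ = scenario_noise_free
    pre_event = Trajectory(traj.system, traj.frames[:3], traj.times[:3])
    series = surface_coverage(pre_event)
    np.testing.assert_allclose(series.coverage, 0.0, atol=1e-12)


def test_coverage_bounded_and_positive_during_dwell(scenario_noise_free):
    traj, truth, _ = scenario_noise_free
    ev = truth[0]
    dwell = Trajectory(
        traj.system,
        traj.frames[ev["dwell_start"]:ev["dwell_start"] + 2],
        traj.times[:2],
    )
    series = surface_coverage(dwell)
    assert np.all(series.coverage > 0)
    assert np.all(series.coverage <= 1)


def test_coverage_equals_one_minus_whole_receptor_rasas(scenario_noise_free):
    traj, truth, _ = scenario_noise_free
    ev = truth[0]
    k = ev["dwell_start"]
    sub = Trajectory(traj.system, traj.frames[k:k + 1], traj.times[:1])
    cov = surface_coverage(sub, probe_radius=2.5)
    receptor_residues = sorted(
        {int(traj.system.residue_seqs[i])
         for i in traj.system.role_indices("receptor")}
    )
    whole = SiteDefinition(
        99, "A", [SiteResidue(s, "ALA") for s in receptor_residues]
    )
    ras = rasas_series(sub, whole, probe_radius=2.5, sidechain_only=False)
    assert cov.coverage[0] == pytest.approx(1 - ras.ratio[0], abs=1e-12)
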