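"""Observable machinery: RDF normalization, local frames/SDF, P(r)/Rg/Dmax,
RMSD superposition, stacking geometry and bulk concentration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucleocg.analysis import (
    AnalysisError,
    bulk_concentration,
    distance_distributions,
    local_frame,
    pr_rg_dmax,
    rdf,
    rmsd,
    sdf,
    stacking_pairs,
)
from nucleocg.ncp_builder import dna_pair_indices, make_synthetic_ncp, replicate_ncp
from nucleocg.structure_io import TrajectoryFrame


def _frames(pos_list, box=400.0):
    return [
        TrajectoryFrame(step=i, box_edge=box, positions=np.asarray(p))
        for i, p in enumerate(pos_list)
    ]


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------
def test_rdf_of_poisson_gas_is_one(rng):
    """Ideal-gas pair statistics give g(r) = 1 within counting error."""
    box = 200.0
    pts = [rng.random((1500, 3)) * box for _ in range(4)]
    res = rdf(pts, pts, box, bin_width_nm=0.5, r_max_nm=9.0, same_set=True)
    good = res.counts > 50
    sigma = 1.0 / np.sqrt(res.counts[good])
    assert np.all(np.abs(res.g[good] - 1.0) < 4.0 * sigma + 0.02)
    assert abs(res.g[good].mean() - 1.0) < 0.01


def test_rdf_two_fixed_particles_single_bin():
    a = [np.array([[0.0, 0.0, 0.0]])]
    b = [np.array([[0.0, 0.0, 50.0]])]  # 5 nm apart
    res = rdf(a, b, 400.0, bin_width_nm=0.2, r_max_nm=10.0)
    occupied = np.flatnonzero(res.counts)
    assert len(occupied) == 1
    assert res.r[occupied[0]] == pytest.approx(5.1, abs=0.1)


def test_rdf_rejects_bad_bin_width():
    with pytest.raises(AnalysisError):
        rdf([], [], 400.0, bin_width_nm=0.0)


# ---------------------------------------------------------------------------
# local frame + SDF
# ---------------------------------------------------------------------------
def test_local_frame_identity_and_handedness():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
    origin, R = local_frame(pos, (0, 1, 2))
    np.testing.assert_allclose(R[0], [1, 0, 0], atol=1e-12)
    np.testing.assert_allclose(R[2], [0, 0, 1], atol=1e-12)
    assert np.linalg.det(R) == pytest.approx(1.0)
    np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)


def test_local_frame_rigid_motion_invariance(rng):
    """Coordinates in the body frame survive any rigid motion to 1e-6 Å."""
    pos = rng.random((30, 3)) * 50
    origin, R = local_frame(pos, (0, 5, 11))
    coords = (pos - origin) @ R.T
    rot = Rotation.random(random_state=7).as_matrix()
    moved = pos @ rot.T + np.array([100.0, -40.0, 3.0])
    origin2, R2 = local_frame(moved, (0, 5, 11))
    coords2 = (moved - origin2) @ R2.T
    np.testing.assert_allclose(coords2, coords, atol=1e-6)


def test_local_frame_collinear_sites_rejected():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    with pytest.raises(AnalysisError, match="collinear"):
        local_frame(pos, (0, 1, 2))


def test_sdf_comoving_particle_in_one_voxel(rng):
    """A particle rigid with the NCP deposits all density in one voxel."""
    base = np.zeros((5, 3))
    base[1] = [10.0, 0, 0]
    base[2] = [0, 10.0, 0]
    base[3] = [3.0, 4.0, 5.0]   # frame sites 0,1,2; species = bead 3
    frames = []
    for i in range(20):
        rot = Rotation.random(random_state=i).as_matrix()
        frames.append(base @ rot.T + np.array([i * 3.0, 0, 0]))
    grid = sdf(_frames(frames), (0, 1, 2), [3], voxel_edge=2.0,
               half_extent=20.0)
    assert (grid.density > 0).sum() == 1
    assert grid.integral() == pytest.approx(1.0)


def test_sdf_uniform_gas_is_flat(rng):
    box = 100.0
    n = 4000
    frames = []
    for _ in range(10):
        pos = rng.random((n + 3, 3)) * box
        pos[0] = [10, 10, 10]
        pos[1] = [30, 10, 10]
        pos[2] = [10, 30, 10]
        frames.append(pos)
    grid = sdf(_frames(frames, box), (0, 1, 2), np.arange(3, n + 3),
               voxel_edge=10.0, half_extent=30.0, box_edge=box)
    expected = n / box**3
    assert grid.density.mean() == pytest.approx(expected, rel=0.05)
    assert grid.density.std() / expected < 0.2


def test_sdf_grid_integral_counts_particles(rng):
    frames = [rng.random((10, 3)) * 20 for _ in range(5)]
    grid = sdf(_frames(frames), (0, 1, 2), np.arange(3, 10),
               voxel_edge=5.0, half_extent=40.0)
    assert grid.integral() == pytest.approx(7.0)


def test_sdf_rejects_bad_voxel():
    with pytest.raises(AnalysisError):
        sdf([], (0, 1, 2), [3], voxel_edge=0.0)


# ---------------------------------------------------------------------------
# P(r) / Rg / Dmax
# ---------------------------------------------------------------------------
def test_pr_two_point_formulas():
    """Two beads at distance d: P a delta at d, Rg = d/2, Dmax = d."""
    d = 10.0
    pos = np.array([[0.0, 0, 0], [0.0, 0, d]])
    curve = pr_rg_dmax(_frames([pos]), [0, 1], bin_width=1.0)
    assert curve.rg == pytest.approx(d / 2.0, rel=0.06)  # bin-centre width
    assert curve.dmax == pytest.approx(d, abs=1.0)
    assert (curve.p > 0).sum() == 1
    assert curve.p.sum() * curve.bin_width == pytest.approx(1.0)


def test_pr_uniform_sphere_radius_of_gyration(rng):
    """Points uniform in a sphere of radius R give Rg = sqrt(3/5) R."""
    R = 30.0
    n = 20000
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    r = R * rng.random(n) ** (1 / 3)
    pos = u * r[:, None]
    curve = pr_rg_dmax(_frames([pos]), np.arange(n), bin_width=0.25)
    assert curve.rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.01)
    assert curve.dmax <= 2 * R + 1.0
    # unit area and no weight beyond Dmax
    assert curve.p.sum() * curve.bin_width == pytest.approx(1.0)
    assert np.all(curve.r <= curve.dmax)


def test_pr_rejects_empty_selection():
    with pytest.raises(AnalysisError):
        pr_rg_dmax(_frames([np.zeros((3, 3))]), [0])


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------
def test_rmsd_identity_and_rigid_motion(rng):
    pos = rng.random((50, 3)) * 30
    assert rmsd(pos, pos) == pytest.approx(0.0, abs=1e-10)
    rot = Rotation.random(random_state=3).as_matrix()
    moved = pos @ rot.T + np.array([5.0, 6.0, 7.0])
    assert rmsd(pos, moved) == pytest.approx(0.0, abs=1e-6)
    assert rmsd(moved, pos) == pytest.approx(rmsd(pos, moved), abs=1e-5)


def test_rmsd_single_displaced_point_bound(rng):
    """One of N points moved by δ: optimal-fit RMSD ≤ δ/√N, and it beats
    every rotation of a brute-force grid."""
    n = 12
    delta = 2.0
    pos = rng.random((n, 3)) * 20
    moved = pos.copy()
    moved[4] += np.array([delta, 0.0, 0.0])
    val = rmsd(pos, moved)
    assert val <= delta / np.sqrt(n) + 1e-9
    # brute-force oracle: no sampled rigid motion does better
    ref0 = pos - pos.mean(axis=0)
    x0 = moved - moved.mean(axis=0)
    best = np.inf
    for rot in Rotation.random(500, random_state=11):
        cand = np.sqrt(((x0 @ rot.as_matrix().T - ref0) ** 2).sum(1).mean())
        best = min(best, cand)
    assert val <= best + 1e-9


def test_rmsd_needs_three_points():
    with pytest.raises(AnalysisError):
        rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# distance distributions
# ---------------------------------------------------------------------------
def test_frozen_helix_distances_match_construction(synthetic_model):
    """On a frozen ideal model the means equal construction, std 0."""
    pos = synthetic_model.positions()
    frames = _frames([pos, pos, pos])
    pairs = dna_pair_indices(synthetic_model)
    stats = distance_distributions(frames, pairs)
    mean, std = stats["cross_strand"]
    assert mean == pytest.approx(18.2, abs=0.05)
    assert std == pytest.approx(0.0, abs=0.05)
    mean, std = stats["dd_consecutive"]
    assert mean == pytest.approx(6.8, abs=1e-6)
    assert std == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------
def test_stacking_coaxial_pair(synthetic_model):
    """Two co-axial NCPs with aligned dyads: angle 0, class 'stacked'."""
    system = replicate_ncp(synthetic_model, 2, 800.0, seed=1)
    pos = system.positions()
    # overwrite with two translated copies of the same oriented NCP
    single = synthetic_model.positions()
    offset = np.array([0.0, 0.0, 60.0])
    pos[:1350] = single + 200.0
    pos[1350:] = single + 200.0 + offset
    system.set_positions(pos)
    contacts = stacking_pairs(_frames([pos], box=800.0), system,
                              cutoff=70.0, box_edge=800.0)
    assert len(contacts) == 1
    c = contacts[0]
    assert c.center_distance == pytest.approx(60.0, abs=1e-6)
    assert c.dyad_angle_deg == pytest.approx(0.0, abs=1e-6)
    assert c.classification == "stacked"


def test_stacking_angle_symmetry(synthetic_model, rng):
    system = replicate_ncp(synthetic_model, 2, 800.0, seed=2)
    single = synthetic_model.positions()
    rot = Rotation.random(random_state=5).as_matrix()
    pos = np.empty((2700, 3))
    pos[:1350] = single + 300.0
    pos[1350:] = single @ rot.T + 300.0 + np.array([55.0, 0, 0])
    system.set_positions(pos)
    frames = _frames([pos], box=800.0)
    c_ab = stacking_pairs(frames, system, cutoff=80.0, box_edge=800.0)[0]
    # swap the two NCPs: angle must be unchanged
    swapped = np.vstack([pos[1350:], pos[:1350]])
    system.set_positions(swapped)
    c_ba = stacking_pairs(_frames([swapped], box=800.0), system,
                          cutoff=80.0, box_edge=800.0)[0]
    assert c_ab.dyad_angle_deg == pytest.approx(c_ba.dyad_angle_deg, abs=1e-6)
    assert 0.0 <= c_ab.dyad_angle_deg <= 90.0


def test_stacking_needs_multiple_ncps(synthetic_model):
    with pytest.raises(AnalysisError):
        stacking_pairs([], synthetic_model)


# ---------------------------------------------------------------------------
# bulk concentration
# ---------------------------------------------------------------------------
def test_bulk_concentration_of_uniform_gas(rng):
    """N ions uniform in the box measure N/V (in mM) anywhere."""
    box = 400.0
    n = 3000
    frames = []
    for _ in range(5):
        pos = np.vstack([np.full((3, 3), 200.0), rng.random((n, 3)) * box])
        frames.append(pos)
    conc = bulk_concentration(
        _frames(frames, box), np.arange(3, n + 3), [np.arange(3)], box
    )
    expected = n / (6.02214076e23 * (box**3 * 1e-27)) * 1e3
    assert conc == pytest.approx(expected, rel=0.15)


def test_bulk_concentration_empty_region_is_zero(synthetic_model):
    pos = synthetic_model.positions() + 200.0
    frames = _frames([pos])
    conc = bulk_concentration(frames, np.array([], dtype=int),
                              [synthetic_model.group("core")], 400.0)
    assert conc == 0.0
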