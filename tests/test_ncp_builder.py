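"""Builder correctness: charge rules, elastic network, DNA geometry,
superhelix wrapping and whole-NCP invariants."""

import numpy as np
import pytest

from nucleocg import constants as C
from nucleocg.forcefield import ForceFieldParams, ForceTables, total_energy_forces
from nucleocg.model import ModelError
from nucleocg.ncp_builder import (
    BuildError,
    SuperhelixPath,
    TailSpec,
    assemble_ncp,
    assign_residue_charge,
    build_core,
    build_dna,
    build_tails,
    dna_pair_indices,
    make_synthetic_ncp,
    replicate_ncp,
    wrap_dna_on_core,
)
from nucleocg.structure_io import ResidueRecord


# ---------------------------------------------------------------------------
# charge rule
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "name,charge",
    [("LYS", 1.0), ("ARG", 1.0), ("ASP", -1.0), ("GLU", -1.0),
     ("GLY", 0.0), ("HIS", 0.0), ("trp", 0.0)],
)
def test_residue_charge_rule(name, charge):
    assert assign_residue_charge(name) == charge


def test_unknown_residue_is_an_error():
    with pytest.raises(BuildError, match="unknown"):
        assign_residue_charge("XYZ")


# ---------------------------------------------------------------------------
# elastic-network core
# ---------------------------------------------------------------------------
def _residues(points, name="GLY"):
    return [
        ResidueRecord("A", i, name, np.asarray(p, float), 1)
        for i, p in enumerate(points)
    ]


def test_four_collinear_points_give_complete_graph():
    """With 4 beads, 3-nearest-neighbour bonding forces the complete graph."""
    beads, bonds = build_core(_residues([(0, 0, 0), (3, 0, 0), (6, 0, 0), (9, 0, 0)]))
    assert len(bonds) == 6
    assert {(b.i, b.j) for b in bonds} == {
        (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)
    }


def test_elastic_network_matches_bruteforce_neighbours(rng):
    """Bond set equals the all-pairs 3-nearest-neighbour union."""
    pts = rng.random((20, 3)) * 30
    _, bonds = build_core(_residues(pts))
    got = {(b.i, b.j) for b in bonds}
    expected = set()
    for i in range(20):
        d = np.linalg.norm(pts - pts[i], axis=1)
        d[i] = np.inf
        for j in np.argsort(d)[:3]:
            expected.add((min(i, int(j)), max(i, int(j))))
    assert got == expected
    # rest lengths are the reference distances
    for b in bonds:
        assert b.r_0 == pytest.approx(np.linalg.norm(pts[b.i] - pts[b.j]))
        assert b.k_b == 5.0


def test_core_rejects_too_few_residues():
    with pytest.raises(BuildError):
        build_core(_residues([(0, 0, 0), (1, 0, 0), (2, 0, 0)]))


def test_core_network_is_connected(synthetic_model):
    """The elastic network holds the octamer as a single rigid body."""
    import networkx as nx

    core = set(synthetic_model.group("core").tolist())
    g = nx.Graph()
    g.add_nodes_from(core)
    g.add_edges_from(
        (b.i, b.j)
        for b in synthetic_model.bonds
        if b.i in core and b.j in core
    )
    assert nx.is_connected(g)


def test_core_charge_inventory(synthetic_model):
    """116 positive, 64 negative, 530 neutral core beads, net +52e."""
    q = synthetic_model.charges()[synthetic_model.group("core")]
    assert ((q > 0).sum(), (q < 0).sum(), (q == 0).sum()) == (116, 64, 530)
    assert q.sum() == pytest.approx(52.0)


# ---------------------------------------------------------------------------
# tails
# ---------------------------------------------------------------------------
def test_tail_bead_and_charge_totals(synthetic_model):
    """Ten tails: 2x(20+35+43+24+13)=270 beads carrying +94e."""
    tails = synthetic_model.group("tails_all")
    assert len(tails) == 270
    assert synthetic_model.charges()[tails].sum() == pytest.approx(94.0)


def test_tail_chain_topology(synthetic_model):
    """Within a tail every bead has 2 bonds except the two chain ends."""
    idx = set(synthetic_model.group("tail_H3_0").tolist())
    deg = {i: 0 for i in idx}
    for b in synthetic_model.bonds:
        if b.i in idx and b.j in idx:
            deg[b.i] += 1
            deg[b.j] += 1
    counts = sorted(deg.values())
    assert counts.count(1) == 2
    assert counts.count(2) == len(idx) - 2


def test_tail_hard_radii_follow_charge(synthetic_model):
    q = synthetic_model.charges()
    r = synthetic_model.hard_radii()
    for i in synthetic_model.group("tails_all"):
        assert r[i] == (0.6 if q[i] != 0 else 0.0)


def test_tail_length_mismatch_is_an_error():
    spec = TailSpec(
        tail_type="H4",
        sequence=["GLY"] * 10,  # H4 tails have 24 residues
        anchor_position=np.zeros(3),
        direction=np.array([1.0, 0, 0]),
    )
    with pytest.raises(BuildError, match="length"):
        build_tails([spec])


# ---------------------------------------------------------------------------
# DNA geometry
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def straight_dna():
    beads, bonds, angles = build_dna(74)
    pos = np.array([b.position for b in beads])
    return beads, bonds, angles, pos


def test_dna_counts_and_charge(straight_dna):
    """74 units -> 370 beads, 296 phosphates carrying -296e."""
    beads = straight_dna[0]
    assert len(beads) == 370
    phosphates = [b for b in beads if b.role == "dna_p"]
    assert len(phosphates) == 296
    assert sum(b.charge for b in beads) == -296.0


def test_dna_construction_geometry(straight_dna):
    """D-D spacing 6.8 Å, 72° twist/unit, cross-strand P-P 18.2 Å."""
    pos = straight_dna[3]
    d = pos[::5]
    np.testing.assert_allclose(
        np.linalg.norm(np.diff(d, axis=0), axis=1), 6.8, atol=1e-9
    )
    p1 = pos[1::5]
    az = np.degrees(np.arctan2(p1[:, 1], p1[:, 0]))
    np.testing.assert_allclose(np.diff(az) % 360.0, 72.0, atol=1e-9)
    cross = np.concatenate(
        [
            np.linalg.norm(pos[1::5] - pos[3::5], axis=1),
            np.linalg.norm(pos[2::5] - pos[4::5], axis=1),
        ]
    )
    np.testing.assert_allclose(cross, 18.2, atol=1e-9)
    # same-strand bonded phosphates at their 6.75 Å equilibrium
    np.testing.assert_allclose(
        np.linalg.norm(pos[1::5] - pos[2::5], axis=1), 6.75, atol=1e-9
    )


def test_dna_masses(straight_dna):
    for b in straight_dna[0]:
        assert b.mass == (4.0 if b.role == "dna_d" else 1.0)


def test_dna_needs_two_units():
    with pytest.raises(BuildError):
        build_dna(1)


def test_straight_dna_is_near_the_bonded_minimum(ff_params):
    """Zero-temperature relaxation barely moves the built helix.

    The idealized B-form placement and the bond/angle table are mutually
    inconsistent at the ~0.03-0.4 Å level, so construction sits near — not
    exactly at — the bonded-term minimum; relaxation under the bonded
    terms alone stays within a fraction of an Å RMSD of construction.
    """
    from nucleocg.model import NCPModel
    from nucleocg.analysis import rmsd

    beads, bonds, angles = build_dna(24)
    model = NCPModel(beads=beads, bonds=bonds, angles=angles, groups={})
    tables = ForceTables(model, ff_params)
    pos = model.positions().copy()
    start = pos.copy()
    for _ in range(3000):
        e, f = total_energy_forces(pos, tables, None, "none")
        fmax = np.abs(f).max()
        if fmax < 1e-4:
            break
        pos += f * min(0.02 / fmax, 0.02)
    assert rmsd(start, pos) < 0.35


# ---------------------------------------------------------------------------
# wrapping
# ---------------------------------------------------------------------------
def test_wrap_nearest_core_matches_bruteforce(rng):
    core = rng.random((200, 3)) * 60 - 30
    path = SuperhelixPath()
    pos, links = wrap_dna_on_core(74, core, path, link_cutoff=100.0)
    assert len(links) == 74
    points = pos[::5]
    for k, (d_idx, core_idx, r0) in enumerate(links):
        d = np.linalg.norm(core - points[k], axis=1)
        assert core_idx == int(np.argmin(d))
        assert r0 == pytest.approx(d.min())


def test_wrap_cutoff_error():
    core = np.zeros((5, 3))  # all at the origin, superhelix radius ~45 Å
    with pytest.raises(BuildError, match="geometry mismatch"):
        wrap_dna_on_core(74, core, link_cutoff=20.0)


def test_superhelix_turn_count(synthetic_model):
    """1.75 turns recovered from the winding of D beads about the axis."""
    d = synthetic_model.positions()[synthetic_model.group("dna_D")]
    az = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    assert abs(az[-1] - az[0]) / (2 * np.pi) == pytest.approx(1.75, abs=1e-6)
    # left-handed: azimuth decreases as z increases
    assert (az[-1] - az[0]) * (d[-1, 2] - d[0, 2]) < 0


def test_wrapped_dna_keeps_local_geometry(synthetic_model):
    """Rotation-minimizing transport preserves the unit geometry."""
    pos = synthetic_model.positions()
    pairs = dna_pair_indices(synthetic_model)
    i, j = pairs["cross_strand"]
    np.testing.assert_allclose(
        np.linalg.norm(pos[i] - pos[j], axis=1), 18.2, atol=0.05
    )
    i, j = pairs["dd_consecutive"]
    np.testing.assert_allclose(
        np.linalg.norm(pos[i] - pos[j], axis=1), 6.8, atol=1e-6
    )


# ---------------------------------------------------------------------------
# whole-particle assembly
# ---------------------------------------------------------------------------
def test_assembled_ncp_counts_and_charges(synthetic_model):
    """1350 beads; component charges +52/+94/-296 summing to -150e."""
    m = synthetic_model
    assert m.n_beads == 1350
    assert m.net_charge() == pytest.approx(-150.0)
    q = m.charges()
    assert q[m.group("core")].sum() == pytest.approx(52.0)
    assert q[m.group("tails_all")].sum() == pytest.approx(94.0)
    dna = np.concatenate([m.group("dna_D"), m.group("dna_P")])
    assert q[dna].sum() == pytest.approx(-296.0)
    m.validate()  # raises on any invariant violation


def test_synthetic_build_is_deterministic():
    a = make_synthetic_ncp(seed=3)
    b = make_synthetic_ncp(seed=3)
    assert a.equals(b, pos_rtol=0.0)
    c = make_synthetic_ncp(seed=4)
    assert not np.allclose(a.positions(), c.positions())


def test_elastic_bond_length_envelope(synthetic_model):
    """Core elastic-network rest lengths stay in a sane [2, 15] Å window."""
    core = set(synthetic_model.group("core").tolist())
    lengths = [
        b.r_0 for b in synthetic_model.bonds
        if b.i in core and b.j in core
    ]
    assert len(lengths) > 710  # deduplicated union of 3-NN bonds
    assert min(lengths) >= 2.0
    assert max(lengths) <= 15.0


def _pdb_line(serial, name, resname, chain, resseq, p):
    return (
        f"ATOM  {serial:>5} {name:<4} {resname:<3} {chain}{resseq:>4}    "
        f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00\n"
    )


def _fake_pdb_from_model(tmp_path, seed=5):
    """Write a synthetic nucleosome as a PDB with the 1KX5 chain layout."""
    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    chain_lengths = {"A": 135, "E": 135, "B": 102, "F": 102,
                     "C": 128, "G": 128, "D": 125, "H": 125}
    from nucleocg.ncp_builder import _synthetic_core_residues
    core = _synthetic_core_residues(np.random.default_rng(seed))
    core_iter = iter(core)
    for chain, length in chain_lengths.items():
        htype = C.CHAIN_MAP_1KX5[chain]
        tail_res = {}
        for ttype, lo, hi in C.TAIL_RANGES[htype]:
            seq = C.TAIL_SEQUENCES[ttype]
            for offset, resseq in enumerate(range(lo, hi + 1)):
                tail_res[resseq] = seq[offset]
        for resseq in range(1, length + 1):
            if resseq in tail_res:
                name = tail_res[resseq]
                p = rng.random(3) * 100 - 50
            else:
                rec = next(core_iter)
                name = rec.residue_name
                p = rec.com
            lines.append(_pdb_line(serial, "CA", name, chain, resseq, p))
            serial += 1
    # two DNA chains of 148 nucleotides on a rough superhelix
    path = SuperhelixPath().points(148)
    for chain in ("I", "J"):
        for resseq in range(1, 149):
            p = path[resseq - 1] + (2.0 if chain == "J" else -2.0)
            lines.append(_pdb_line(serial, "P", "DA", chain, resseq, p))
            serial += 1
    pdb = tmp_path / "synthetic_ncp.pdb"
    pdb.write_text("".join(lines))
    return pdb


def test_pdb_and_synthetic_paths_agree_structurally(tmp_path):
    """Crystal-derived and synthetic builds share counts and inventory."""
    pdb = _fake_pdb_from_model(tmp_path)
    from_pdb = assemble_ncp(str(pdb))
    synth = make_synthetic_ncp(seed=5)
    assert from_pdb.n_beads == synth.n_beads
    assert from_pdb.net_charge() == synth.net_charge()
    for grp in ("core", "tails_all", "dna_D", "dna_P"):
        assert len(from_pdb.group(grp)) == len(synth.group(grp))
    assert len(from_pdb.bonds) == len(synth.bonds)
    assert len(from_pdb.angles) == len(synth.angles)
    q1 = np.sort(from_pdb.charges())
    q2 = np.sort(synth.charges())
    np.testing.assert_array_equal(q1, q2)


def test_replicate_places_separated_copies(synthetic_model):
    system = replicate_ncp(synthetic_model, 4, 400.0, seed=9)
    assert system.n_beads == 4 * 1350
    assert system.net_charge() == pytest.approx(-600.0)
    centers = np.array(
        [
            system.positions()[system.group(f"ncp{i}/core")].mean(axis=0)
            for i in range(4)
        ]
    )
    for i in range(4):
        for j in range(i + 1, 4):
            d = centers[i] - centers[j]
            d -= 400.0 * np.round(d / 400.0)
            assert np.linalg.norm(d) >= 115.0
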