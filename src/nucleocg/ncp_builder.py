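"""Construct the coarse-grained nucleosome core particle.

The NCP is assembled from four ingredients:

* a *core*: 710 beads (one per globular histone residue) tied into an
  elastic network — every bead harmonically bonded to its three nearest
  neighbours at the reference distance;
* ten flexible *tails* (two copies each of the H2A N-tail, H2B, H3, H4 and
  the short H2A C-tail) as linear bead chains, one bead per residue,
  charge by residue type, anchored to the core at one end;
* *DNA*: 74 five-bead units (one central D bead per two base pairs plus
  four phosphates placed on an idealized B-form double helix), wrapped on
  a 1.75-turn left-handed superhelix;
* *link bonds* tying each D bead to its nearest core bead, which is what
  holds the DNA wrapped in place of the ionic/hydrogen bonding of the real
  particle.

Both build paths — from a crystal structure or from the bundled synthetic
generator — produce models with identical bead counts, charge inventory
(+52e core, +94e tails, −296e DNA; net −150e) and bonded-term counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .model import AngleTerm, Bead, BondTerm, ModelError, NCPModel
from .structure_io import ResidueRecord, read_pdb_residues


class BuildError(ValueError):
    pass


# ---------------------------------------------------------------------------
# charge rule
# ---------------------------------------------------------------------------
def assign_residue_charge(residue_name: str) -> float:
    """Charge in e for a standard amino-acid 3-letter code.

    Lys/Arg -> +1, Asp/Glu -> -1, other standard residues 0. Unknown codes
    raise (no silent zero).
    """
    name = residue_name.upper()
    if name in C.POSITIVE_RESIDUES:
        return 1.0
    if name in C.NEGATIVE_RESIDUES:
        return -1.0
    if name in C.NEUTRAL_RESIDUES:
        return 0.0
    raise BuildError(f"unknown amino-acid code {residue_name!r}")


# ---------------------------------------------------------------------------
# octamer core: one bead per residue + elastic network
# ---------------------------------------------------------------------------
def build_core(
    globular_residues,
    k_b: float = C.CORE_BOND_K,
    n_neighbors: int = C.CORE_NEIGHBOURS,
):
    """Core beads and the 3-nearest-neighbour elastic network.

    Each bead is bonded to its ``n_neighbors`` nearest beads; the union is
    deduplicated, so a bead may end up carrying more bonds than that. Bond
    rest lengths are the reference (crystal) distances. Equidistant
    neighbour candidates are resolved toward the lower bead index, keeping
    builds deterministic.

    Returns (beads, bonds) with local indices 0..n-1.
    """
    residues = list(globular_residues)
    if len(residues) <= n_neighbors:
        raise BuildError(
            f"need more than {n_neighbors} residues, got {len(residues)}"
        )
    pos = np.array([r.com for r in residues], dtype=float)
    beads = [
        Bead(
            index=i,
            role="core",
            sub_label=getattr(r, "chain_id", "") or "core",
            charge=assign_residue_charge(r.residue_name),
            hard_radius=0.0,
            mass=1.0,
            position=pos[i],
        )
        for i, r in enumerate(residues)
    ]
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    pairs: set[tuple[int, int]] = set()
    for i in range(len(residues)):
        order = np.argsort(d2[i], kind="stable")[:n_neighbors]
        for j in order:
            pairs.add((min(i, int(j)), max(i, int(j))))
    bonds = [
        BondTerm(i, j, k_b, float(math.sqrt(d2[i, j])))
        for i, j in sorted(pairs)
    ]
    return beads, bonds


# ---------------------------------------------------------------------------
# histone tails
# ---------------------------------------------------------------------------
@dataclass
class TailSpec:
    """One tail: type, residue sequence (anchor end first) and geometry.

    Either explicit per-bead ``positions`` (crystal path) or an
    ``anchor_position`` plus outward ``direction`` (synthetic path: beads
    on a straight line at the peptide contour spacing).
    """

    tail_type: str
    sequence: list[str]
    anchor_position: np.ndarray | None = None
    direction: np.ndarray | None = None
    positions: np.ndarray | None = None


def build_tails(tail_specs: list[TailSpec], start_index: int = 0):
    """Tail beads + chain bonds for ten tails.

    Returns (beads, bonds, slices) where slices maps (tail_type, copy) to
    the bead index ranges; indices start at ``start_index``. The bond to
    the core anchor is added by the assembler, which knows the core.
    """
    counts: dict[str, int] = {}
    for spec in tail_specs:
        counts[spec.tail_type] = counts.get(spec.tail_type, 0) + 1
    if sorted(counts) == sorted(C.TAIL_TYPES) and any(
        v != 2 for v in counts.values()
    ):
        raise BuildError("expected two copies of each tail type")
    beads: list[Bead] = []
    bonds: list[BondTerm] = []
    slices: dict[tuple[str, int], range] = {}
    copies: dict[str, int] = {}
    idx = start_index
    for spec in tail_specs:
        expected = C.TAIL_LENGTHS.get(spec.tail_type)
        if expected is not None and len(spec.sequence) != expected:
            raise BuildError(
                f"tail {spec.tail_type}: sequence length {len(spec.sequence)}"
                f" != declared {expected}"
            )
        if spec.positions is not None:
            pos = np.asarray(spec.positions, dtype=float)
            if len(pos) != len(spec.sequence):
                raise BuildError("tail positions/sequence length mismatch")
        else:
            d = np.asarray(spec.direction, dtype=float)
            d = d / np.linalg.norm(d)
            steps = np.arange(1, len(spec.sequence) + 1)[:, None]
            pos = np.asarray(spec.anchor_position, float) + C.TAIL_BOND_R0 * steps * d
        first = idx
        for resname, p in zip(spec.sequence, pos):
            q = assign_residue_charge(resname)
            beads.append(
                Bead(
                    index=idx,
                    role="tail",
                    sub_label=spec.tail_type,
                    charge=q,
                    hard_radius=C.TAIL_CHARGED_RADIUS if q != 0 else 0.0,
                    mass=1.0,
                    position=p,
                )
            )
            if idx > first:
                bonds.append(BondTerm(idx - 1, idx, C.TAIL_BOND_K, C.TAIL_BOND_R0))
            idx += 1
        copy = copies.get(spec.tail_type, 0)
        copies[spec.tail_type] = copy + 1
        slices[(spec.tail_type, copy)] = range(first, idx)
    return beads, bonds, slices


# ---------------------------------------------------------------------------
# DNA: five-bead / two-bp units on an idealized B-form double helix
# ---------------------------------------------------------------------------
def _unit_local_coords():
    """Per-unit cylindrical coordinates (azimuth deg, axial offset) of the
    four phosphates: P1/P2 on strand 1, P3/P4 on strand 2.

    The phosphate radius is fixed by the same-strand P-P bond length and
    the 36°/bp twist; the strand-2 phase by the ideal-B cross-strand
    (same-bp) distance of 18.2 Å. P1/P3 sit on the first bp of the unit
    (axial offset -1.7 Å), P2/P4 on the second (+1.7 Å).
    """
    tw = C.DNA_TWIST_PER_UNIT / 2.0  # 36° per bp
    ph = C.DNA_STRAND_PHASE
    half = C.DNA_RISE / 2.0
    return [
        (0.0, -half),       # P1
        (tw, +half),        # P2
        (ph, -half),        # P3
        (ph + tw, +half),   # P4
    ]


def _place_units(path_points: np.ndarray, frames: np.ndarray):
    """Bead positions for all units given D-bead path points and local
    orthonormal frames (normal, binormal, tangent) per unit."""
    n_units = len(path_points)
    local = _unit_local_coords()
    rho = C.DNA_P_RADIUS
    pos = np.empty((5 * n_units, 3))
    for k in range(n_units):
        nhat, bhat, that = frames[k]
        pos[5 * k] = path_points[k]
        for m, (az, dz) in enumerate(local):
            a = math.radians(az + C.DNA_TWIST_PER_UNIT * k)
            pos[5 * k + 1 + m] = (
                path_points[k]
                + rho * (math.cos(a) * nhat + math.sin(a) * bhat)
                + dz * that
            )
    return pos


def _straight_path(n_units: int):
    z = C.DNA_DD_SPACING * np.arange(n_units)
    points = np.zeros((n_units, 3))
    points[:, 2] = z
    frames = np.tile(np.eye(3)[None, (0, 1, 2)], (n_units, 1, 1))
    return points, frames


def _dna_topology(n_units: int, start_index: int = 0):
    """Bond and angle terms of the helical DNA (local indices)."""
    def D(k):
        return start_index + 5 * k

    def P(k, m):  # m = 1..4
        return start_index + 5 * k + m

    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    r_dp, k_dp = C.DNA_BOND_DP
    r_dd, k_dd = C.DNA_BOND_DD
    r_pp, k_pp = C.DNA_BOND_PP_STRAND
    r_mg, k_mg = C.DNA_BOND_PP_MINOR
    for k in range(n_units):
        for m in range(1, 5):
            bonds.append(BondTerm(D(k), P(k, m), k_dp, r_dp))
        bonds.append(BondTerm(P(k, 1), P(k, 2), k_pp, r_pp))
        bonds.append(BondTerm(P(k, 3), P(k, 4), k_pp, r_pp))
        if k + 1 < n_units:
            bonds.append(BondTerm(D(k), D(k + 1), k_dd, r_dd))
            bonds.append(BondTerm(P(k, 2), P(k + 1, 1), k_pp, r_pp))
            bonds.append(BondTerm(P(k, 4), P(k + 1, 3), k_pp, r_pp))
            bonds.append(BondTerm(P(k, 1), P(k + 1, 3), k_mg, r_mg))
            bonds.append(BondTerm(P(k, 2), P(k + 1, 4), k_mg, r_mg))
    a_ddd, k_ddd = C.DNA_ANGLE_DDD
    a_str, k_str = C.DNA_ANGLE_STRAND
    a_pdp, k_pdp = C.DNA_ANGLE_PDP
    for k in range(n_units):
        angles.append(
            AngleTerm(P(k, 1), D(k), P(k, 3), k_pdp, math.radians(a_pdp))
        )
        angles.append(
            AngleTerm(P(k, 2), D(k), P(k, 4), k_pdp, math.radians(a_pdp))
        )
        if k + 2 < n_units:
            angles.append(
                AngleTerm(D(k), D(k + 1), D(k + 2), k_ddd, math.radians(a_ddd))
            )
        if k + 1 < n_units:
            angles.append(
                AngleTerm(P(k, 1), P(k, 2), P(k + 1, 1), k_str, math.radians(a_str))
            )
            angles.append(
                AngleTerm(P(k, 2), P(k + 1, 1), P(k + 1, 2), k_str, math.radians(a_str))
            )
            angles.append(
                AngleTerm(P(k, 3), P(k, 4), P(k + 1, 3), k_str, math.radians(a_str))
            )
            angles.append(
                AngleTerm(P(k, 4), P(k + 1, 3), P(k + 1, 4), k_str, math.radians(a_str))
            )
    return bonds, angles


def _dna_beads(n_units: int, positions: np.ndarray, start_index: int = 0):
    beads = []
    idx = start_index
    for k in range(n_units):
        beads.append(
            Bead(idx, "dna_d", "D", 0.0, C.DNA_D_HARD_RADIUS, C.DNA_D_MASS,
                 positions[5 * k])
        )
        idx += 1
        for m in range(4):
            beads.append(
                Bead(idx, "dna_p", f"P{m + 1}", C.DNA_P_CHARGE,
                     C.DNA_P_HARD_RADIUS, 1.0, positions[5 * k + 1 + m])
            )
            idx += 1
    return beads


def build_dna(n_units: int = C.N_DNA_UNITS, start_index: int = 0):
    """Straight helical DNA of ``n_units`` five-bead units.

    Returns (beads, bonds, angles): D beads 6.8 Å apart on the z axis,
    phosphate frame rotated 72° per unit, cross-strand same-bp phosphate
    distance 18.2 Å (idealized B form).
    """
    if n_units < 2:
        raise BuildError(f"need at least 2 DNA units, got {n_units}")
    points, frames = _straight_path(n_units)
    pos = _place_units(points, frames)
    beads = _dna_beads(n_units, pos, start_index)
    bonds, angles = _dna_topology(n_units, start_index)
    return beads, bonds, angles


@dataclass
class SuperhelixPath:
    """Parametric left-handed superhelix for the wrapped DNA path."""

    radius: float = C.superhelix_radius()
    pitch: float = C.SUPERHELIX_PITCH
    turns: float = C.SUPERHELIX_TURNS
    center: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 0.0, 1.0)

    def points(self, n_units: int) -> np.ndarray:
        theta_tot = 2.0 * np.pi * self.turns
        t = np.linspace(-0.5, 0.5, n_units)
        theta = theta_tot * t
        c = self.pitch / (2.0 * np.pi)
        local = np.stack(
            [
                self.radius * np.cos(theta),
                -self.radius * np.sin(theta),  # left-handed winding
                c * theta,
            ],
            axis=1,
        )
        rot = _rotation_to(np.asarray(self.axis, float))
        return local @ rot.T + np.asarray(self.center, float)


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``axis``."""
    z = np.array([0.0, 0.0, 1.0])
    a = axis / np.linalg.norm(axis)
    v = np.cross(z, a)
    s = np.linalg.norm(v)
    c = float(z @ a)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _transport_frames(points: np.ndarray) -> np.ndarray:
    """Rotation-minimizing (double-reflection) frames along a path."""
    n = len(points)
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    frames = np.empty((n, 3, 3))
    # initial normal: component of the outward radial direction normal to t
    seed = points[0] - points.mean(axis=0)
    seed -= (seed @ tangents[0]) * tangents[0]
    if np.linalg.norm(seed) < 1e-9:
        seed = np.array([1.0, 0.0, 0.0])
        seed -= (seed @ tangents[0]) * tangents[0]
    nvec = seed / np.linalg.norm(seed)
    frames[0] = (nvec, np.cross(tangents[0], nvec), tangents[0])
    for k in range(n - 1):
        n0, _, t0 = frames[k]
        v1 = points[k + 1] - points[k]
        c1 = v1 @ v1
        nL = n0 - (2.0 / c1) * (v1 @ n0) * v1
        tL = t0 - (2.0 / c1) * (v1 @ t0) * v1
        v2 = tangents[k + 1] - tL
        c2 = v2 @ v2
        n1 = nL if c2 < 1e-14 else nL - (2.0 / c2) * (v2 @ nL) * v2
        n1 -= (n1 @ tangents[k + 1]) * tangents[k + 1]
        n1 /= np.linalg.norm(n1)
        frames[k + 1] = (n1, np.cross(tangents[k + 1], n1), tangents[k + 1])
    return frames


def wrap_dna_on_core(
    n_units: int,
    core_positions: np.ndarray,
    path_spec: SuperhelixPath | np.ndarray | None = None,
    start_index: int = 0,
    link_cutoff: float = 30.0,
):
    """Position DNA on the superhelix and link each D bead to the core.

    ``path_spec`` is either a :class:`SuperhelixPath` (default: canonical
    1.75-turn geometry) or an explicit (n_units, 3) array of D-bead path
    points (crystal path). Returns (positions, link_bonds) where each link
    bond ties D bead k to its nearest core bead with k_b = 5 kT/Å² at the
    current distance. Equidistant core candidates resolve to the lower
    index.
    """
    core_positions = np.asarray(core_positions, dtype=float)
    if path_spec is None:
        path_spec = SuperhelixPath()
    if isinstance(path_spec, SuperhelixPath):
        points = path_spec.points(n_units)
    else:
        points = np.asarray(path_spec, dtype=float)
        if points.shape != (n_units, 3):
            raise BuildError("explicit path must be (n_units, 3)")
    frames = _transport_frames(points)
    positions = _place_units(points, frames)
    links = []
    for k in range(n_units):
        d = np.linalg.norm(core_positions - points[k], axis=1)
        nearest = int(np.argmin(d))  # argmin -> lowest index on ties
        if d[nearest] > link_cutoff:
            raise BuildError(
                f"D bead {k} is {d[nearest]:.1f} Å from the nearest core bead"
                f" (cutoff {link_cutoff} Å): geometry mismatch"
            )
        links.append((start_index + 5 * k, nearest, float(d[nearest])))
    return positions, links


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------
def _synthetic_core_residues(rng: np.random.Generator):
    """710 pseudo-residues filling a wedge-shaped octamer cylinder.

    Beads are placed by seeded rejection sampling with a minimum spacing;
    the wedge tapers from 57 to 45 Å height around the azimuth. Charges
    match the crystal inventory (116 Lys-like, 64 Asp-like, 530 neutral),
    with positive residues biased toward large radius, i.e. toward the DNA
    path, emulating the charge mosaic of the octamer surface.
    """
    radius = C.SYNTH_CORE_RADIUS
    hmin, hmax = C.SYNTH_CORE_HEIGHT_MIN, C.SYNTH_CORE_HEIGHT_MAX
    spacing2 = C.SYNTH_CORE_MIN_SPACING**2
    pos = np.empty((C.N_CORE_BEADS, 3))
    n = 0
    attempts = 0
    while n < C.N_CORE_BEADS:
        attempts += 1
        if attempts > 500_000:
            raise BuildError("synthetic core packing failed")
        u = rng.random(3)
        r = radius * math.sqrt(u[0])
        phi = 2.0 * math.pi * u[1]
        h = hmin + (hmax - hmin) * 0.5 * (1.0 + math.cos(phi))
        p = np.array([r * math.cos(phi), r * math.sin(phi), (u[2] - 0.5) * h])
        if n and (((pos[:n] - p) ** 2).sum(axis=1) < spacing2).any():
            continue
        pos[n] = p
        n += 1
    rxy = np.hypot(pos[:, 0], pos[:, 1])
    w = np.exp((rxy - radius) / 8.0)
    n_pos, n_neg, _ = C.CORE_CHARGE_COUNTS
    pos_idx = rng.choice(C.N_CORE_BEADS, size=n_pos, replace=False, p=w / w.sum())
    rest = np.setdiff1d(np.arange(C.N_CORE_BEADS), pos_idx)
    neg_idx = rng.choice(rest, size=n_neg, replace=False)
    names = np.full(C.N_CORE_BEADS, "GLY", dtype=object)
    names[pos_idx] = "LYS"
    names[neg_idx] = "ASP"
    histones = ("H3", "H4", "H2A", "H2B")
    return [
        ResidueRecord(
            chain_id=histones[i % 4],
            residue_index=i,
            residue_name=names[i],
            com=pos[i],
            n_atoms=1,
        )
        for i in range(C.N_CORE_BEADS)
    ]


def _synthetic_tail_specs():
    """Anchor points/directions for the ten tails on the synthetic core.

    H2A and H4 tails leave from the flat top/bottom faces; H2B, H3 and the
    H2A C-tail exit on the lateral surface between the DNA gyres. The
    second copy of each tail is related by the pseudo two-fold of the
    particle (azimuth + 180°, z mirrored).
    """
    r_face, r_side = 18.0, 29.0
    z_face, z_side = 26.0, 6.0
    layout = [
        ("H2A", 40.0, z_face, np.array([0.4, 0.3, 1.0])),
        ("H4", 210.0, z_face, np.array([-0.4, -0.2, 1.0])),
        ("H2B", 100.0, z_side, None),
        ("H3", 300.0, -z_side, None),
        ("H2A-C", 170.0, 0.0, None),
    ]
    specs = []
    for name, phi_deg, z, direction in layout:
        for copy in range(2):
            phi = math.radians(phi_deg + 180.0 * copy)
            sign = 1.0 if copy == 0 else -1.0
            on_face = direction is not None
            r0 = r_face if on_face else r_side
            anchor = np.array(
                [r0 * math.cos(phi), r0 * math.sin(phi), sign * z]
            )
            if on_face:
                d = direction * np.array([1.0, 1.0, sign])
            else:
                d = np.array([math.cos(phi), math.sin(phi), 0.15 * sign])
            specs.append(
                TailSpec(
                    tail_type=name,
                    sequence=list(C.TAIL_SEQUENCES[name]),
                    anchor_position=anchor,
                    direction=d / np.linalg.norm(d),
                )
            )
    return specs


def _greedy_far_triplet(pos: np.ndarray) -> list[int]:
    centroid = pos.mean(axis=0)
    a = int(np.argmax(((pos - centroid) ** 2).sum(axis=1)))
    b = int(np.argmax(((pos - pos[a]) ** 2).sum(axis=1)))
    dmin = np.minimum(
        np.linalg.norm(pos - pos[a], axis=1), np.linalg.norm(pos - pos[b], axis=1)
    )
    c = int(np.argmax(dmin))
    return [a, b, c]


def _assemble(core_residues, tail_specs, dna_path=None) -> NCPModel:
    core_beads, core_bonds = build_core(core_residues)
    core_pos = np.array([b.position for b in core_beads])
    tail_beads, tail_bonds, slices = build_tails(
        tail_specs, start_index=len(core_beads)
    )
    bonds = list(core_bonds) + list(tail_bonds)
    # anchor each tail's first bead to the nearest core bead
    for (_, _), rng_ in slices.items():
        first = rng_.start
        p = tail_beads[first - len(core_beads)].position
        nearest = int(np.argmin(((core_pos - p) ** 2).sum(axis=1)))
        bonds.append(BondTerm(nearest, first, C.TAIL_BOND_K, C.TAIL_BOND_R0))
    dna_start = len(core_beads) + len(tail_beads)
    dna_pos, links = wrap_dna_on_core(
        C.N_DNA_UNITS, core_pos, dna_path, start_index=dna_start
    )
    dna_beads = _dna_beads(C.N_DNA_UNITS, dna_pos, dna_start)
    dna_bonds, dna_angles = _dna_topology(C.N_DNA_UNITS, dna_start)
    bonds += dna_bonds
    for d_idx, core_idx, r0 in links:
        bonds.append(BondTerm(core_idx, d_idx, C.LINK_BOND_K, r0))

    beads = core_beads + tail_beads + dna_beads
    groups: dict[str, np.ndarray] = {
        "core": np.arange(len(core_beads)),
        "tails_all": np.arange(len(core_beads), dna_start),
    }
    for (ttype, copy), rng_ in slices.items():
        groups[f"tail_{ttype}_{copy}"] = np.arange(rng_.start, rng_.stop)
    d_idx = dna_start + 5 * np.arange(C.N_DNA_UNITS)
    groups["dna_D"] = d_idx
    groups["dna_P"] = np.sort(
        np.concatenate([d_idx + m for m in range(1, 5)])
    )
    groups["dna_strand1"] = np.sort(np.concatenate([d_idx + 1, d_idx + 2]))
    groups["dna_strand2"] = np.sort(np.concatenate([d_idx + 3, d_idx + 4]))
    centroid = core_pos.mean(axis=0)
    center_bead = int(np.argmin(((core_pos - centroid) ** 2).sum(axis=1)))
    mid_d = int(d_idx[C.N_DNA_UNITS // 2])
    groups["dyad_sites"] = np.array([center_bead, mid_d])
    groups["frame_sites"] = np.array(_greedy_far_triplet(core_pos))
    # superhelix axis from the D-bead path (least-varying direction)
    dpos = dna_pos[::5] - dna_pos[::5].mean(axis=0)
    _, _, vt = np.linalg.svd(dpos, full_matrices=False)
    axis = vt[2]
    ax_a = int(np.argmin(((core_pos - (centroid + 22 * axis)) ** 2).sum(axis=1)))
    ax_b = int(np.argmin(((core_pos - (centroid - 22 * axis)) ** 2).sum(axis=1)))
    groups["axis_sites"] = np.array([ax_a, ax_b])

    model = NCPModel(
        beads=beads, bonds=bonds, angles=list(dna_angles), groups=groups
    )
    model.validate()
    return model


def make_synthetic_ncp(seed: int = 0) -> NCPModel:
    """Deterministic synthetic NCP emulating the crystal-derived inventory."""
    rng = np.random.default_rng(seed)
    residues = _synthetic_core_residues(rng)
    return _assemble(residues, _synthetic_tail_specs())


# ---------------------------------------------------------------------------
# crystal-structure path
# ---------------------------------------------------------------------------
def split_histone_residues(records, chain_map=None):
    """Partition histone residues into globular core and per-tail lists.

    Returns (globular, tails) where tails maps (tail_type, copy) to the
    residue list ordered anchor-end first. Nucleotide residues are ignored.
    """
    chain_map = dict(C.CHAIN_MAP_1KX5 if chain_map is None else chain_map)
    globular = []
    tails: dict[tuple[str, int], list] = {}
    copies: dict[str, int] = {}
    chains: dict[str, list] = {}
    for rec in records:
        chains.setdefault(rec.chain_id, []).append(rec)
    for chain_id, recs in chains.items():
        htype = chain_map.get(chain_id)
        if htype is None or htype == "DNA":
            continue
        recs = sorted(recs, key=lambda r: r.residue_index)
        ranges = C.TAIL_RANGES[htype]
        tail_ids: dict[str, list] = {}
        for ttype, lo, hi in ranges:
            tail_ids[ttype] = [r for r in recs if lo <= r.residue_index <= hi]
        in_tail = {
            id(r) for members in tail_ids.values() for r in members
        }
        globular += [r for r in recs if id(r) not in in_tail]
        for ttype, members in tail_ids.items():
            # N-terminal tails attach via their highest-numbered residue,
            # the H2A C-tail via its lowest: anchor end goes first.
            anchored = members if ttype.endswith("-C") else members[::-1]
            copy = copies.get(ttype, 0)
            copies[ttype] = copy + 1
            tails[(ttype, copy)] = anchored
    return globular, tails


def assemble_ncp(source: str = "synthetic", seed: int = 0,
                 chain_map=None) -> NCPModel:
    """Build one NCP from ``'synthetic'`` or from a PDB file path.

    The crystal path takes residue centres of mass for core and tail beads
    and fits the superhelix axis from the nucleotide positions; the DNA
    beads themselves are placed on the parametric superhelix.
    """
    if source == "synthetic":
        return make_synthetic_ncp(seed)
    records = read_pdb_residues(source)
    chain_map = dict(C.CHAIN_MAP_1KX5 if chain_map is None else chain_map)
    histones = [
        r for r in records
        if chain_map.get(r.chain_id) not in (None, "DNA")
    ]
    if not histones:
        raise BuildError("no histone-chain residues found in structure")
    globular, tails = split_histone_residues(records, chain_map)
    if len(globular) != C.N_CORE_BEADS:
        raise BuildError(
            f"tail split left {len(globular)} globular residues, "
            f"expected {C.N_CORE_BEADS}"
        )
    specs = []
    for ttype in C.TAIL_TYPES:
        for copy in range(2):
            members = tails.get((ttype, copy))
            if not members:
                raise BuildError(f"missing tail {ttype} copy {copy}")
            specs.append(
                TailSpec(
                    tail_type=ttype,
                    sequence=[r.residue_name for r in members],
                    positions=np.array([r.com for r in members]),
                )
            )
    nuc = [r for r in records if chain_map.get(r.chain_id) == "DNA"]
    path = SuperhelixPath()
    if nuc:
        npos = np.array([r.com for r in nuc])
        center = npos.mean(axis=0)
        _, _, vt = np.linalg.svd(npos - center, full_matrices=False)
        path = SuperhelixPath(center=tuple(center), axis=tuple(vt[2]))
    return _assemble(globular, specs, path)


# ---------------------------------------------------------------------------
# multi-NCP systems
# ---------------------------------------------------------------------------
def replicate_ncp(
    model: NCPModel,
    n_ncp: int,
    box_edge: float,
    seed: int = 0,
    min_center_sep: float = 115.0,
    max_tries: int = 20_000,
) -> NCPModel:
    """Place ``n_ncp`` randomly rotated copies in a cubic box.

    Copies are centred at uniform-random positions with pairwise
    minimum-image centre separation of at least ``min_center_sep`` Å.
    Groups are prefixed ``ncp<i>/``; deterministic per seed.
    """
    if n_ncp < 1:
        raise BuildError("n_ncp must be >= 1")
    rng = np.random.default_rng(seed)
    base_pos = model.positions()
    centroid = base_pos[model.group("core")].mean(axis=0)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_ncp:
        tries += 1
        if tries > max_tries:
            raise BuildError("could not place NCPs without overlap")
        cand = rng.random(3) * box_edge
        ok = True
        for c in centers:
            d = cand - c
            d -= box_edge * np.round(d / box_edge)
            if np.linalg.norm(d) < min_center_sep:
                ok = False
                break
        if ok:
            centers.append(cand)
    beads: list[Bead] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    groups: dict[str, np.ndarray] = {}
    n = model.n_beads
    for i in range(n_ncp):
        rot = _random_rotation(rng)
        pos = (base_pos - centroid) @ rot.T + centers[i]
        off = i * n
        for b in model.beads:
            beads.append(
                Bead(off + b.index, b.role, b.sub_label, b.charge,
                     b.hard_radius, b.mass, pos[b.index])
            )
        bonds += [
            BondTerm(bd.i + off, bd.j + off, bd.k_b, bd.r_0)
            for bd in model.bonds
        ]
        angles += [
            AngleTerm(a.i + off, a.j + off, a.k + off, a.k_a, a.phi_0)
            for a in model.angles
        ]
        for g, idx in model.groups.items():
            groups[f"ncp{i}/{g}"] = np.asarray(idx) + off
    return NCPModel(beads=beads, bonds=bonds, angles=angles, groups=groups,
                    n_ncp=n_ncp)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def dna_pair_indices(model: NCPModel, prefix: str = "") -> dict[str, tuple]:
    """Index pairs of the named DNA distance classes.

    Keys: ``cross_strand`` (opposite phosphates of the same bp),
    ``strand_consecutive`` (neighbouring phosphates along a strand) and
    ``dd_consecutive`` (neighbouring D beads).
    """
    d = model.group(prefix + "dna_D")
    pairs = {
        "cross_strand": (
            np.concatenate([d + 1, d + 2]),
            np.concatenate([d + 3, d + 4]),
        ),
        "dd_consecutive": (d[:-1], d[1:]),
    }
    s1_i = np.concatenate([d + 1, (d + 2)[:-1]])
    s1_j = np.concatenate([d + 2, (d + 1)[1:]])
    s2_i = np.concatenate([d + 3, (d + 4)[:-1]])
    s2_j = np.concatenate([d + 4, (d + 3)[1:]])
    pairs["strand_consecutive"] = (
        np.concatenate([s1_i, s2_i]),
        np.concatenate([s1_j, s2_j]),
    )
    return pairs
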