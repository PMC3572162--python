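"""File formats: PDB reading, topology files, XYZ-dialect trajectories.

The topology format is a self-describing versioned text file (bead table,
bond table, angle table, named groups) chosen for diffability and language
neutrality. Trajectories are XYZ-style text blocks with a
``# step N box B`` comment line per frame. Coordinates are Å everywhere;
no unit conversion happens inside I/O.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .model import AngleTerm, Bead, BondTerm, NCPModel

TOPOLOGY_MAGIC = "# nucleocg topology"
TOPOLOGY_VERSION = 1


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------
@dataclass
class ResidueRecord:
    """One residue of a crystal structure collapsed to its centre of mass.

    ``com`` is the unweighted mean of the constituent atom coordinates
    unless mass weighting was requested at read time.
    """

    chain_id: str
    residue_index: int
    residue_name: str
    com: np.ndarray
    n_atoms: int

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)
        if self.n_atoms < 1:
            raise ValueError("residue must contain at least one atom")


def read_pdb_residues(path, mass_weighted: bool = False) -> list[ResidueRecord]:
    """Residue-level records from a PDB file.

    One record per (chain, residue index); coordinates in Å. Centres of
    mass use the unweighted atom-coordinate mean by default; pass
    ``mass_weighted=True`` to weight by element mass. Raises
    :class:`ParseError` when the file holds no ATOM/HETATM records or a
    coordinate field fails to parse (naming the line number).
    """
    # A light pre-scan validates coordinate fields with line numbers, which
    # the Bio.PDB parser used below does not report.
    with open(path) as fh:
        lines = fh.readlines()
    n_atom_lines = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_atom_lines += 1
            if len(line) < 54:
                raise ParseError(f"{path}: truncated ATOM record on line {lineno}")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}: malformed coordinate field on line {lineno}:"
                        f" {line[lo:hi]!r}"
                    ) from None
    if n_atom_lines == 0:
        raise ParseError(f"{path}: no atoms (no ATOM/HETATM records)")

    from Bio.PDB import PDBParser
    from Bio.Data.IUPACData import atom_weights

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    records: list[ResidueRecord] = []
    for pdb_model in structure:
        for chain in pdb_model:
            for residue in chain:
                coords = []
                weights = []
                for atom in residue:
                    coords.append(atom.coord)
                    if mass_weighted:
                        el = (atom.element or "C").capitalize()
                        weights.append(atom_weights.get(el, 12.0))
                if not coords:
                    continue
                coords = np.asarray(coords, dtype=float)
                if mass_weighted:
                    w = np.asarray(weights)
                    com = (coords * w[:, None]).sum(axis=0) / w.sum()
                else:
                    com = coords.mean(axis=0)
                records.append(
                    ResidueRecord(
                        chain_id=chain.id,
                        residue_index=residue.id[1],
                        residue_name=residue.get_resname().strip(),
                        com=com,
                        n_atoms=len(coords),
                    )
                )
        break  # first model only
    if not records:
        raise ParseError(f"{path}: no atoms")
    return records


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------
def write_topology(model: NCPModel, path_or_file) -> None:
    """Write a model to the versioned text topology format."""
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    fh = open(path_or_file, "w") if own else path_or_file
    try:
        fh.write(f"{TOPOLOGY_MAGIC}\n")
        fh.write(f"version {TOPOLOGY_VERSION}\n")
        fh.write(f"n_beads {model.n_beads}\n")
        fh.write(f"n_ncp {model.n_ncp}\n")
        fh.write("[beads]\n")
        for b in model.beads:
            fh.write(
                f"{b.index} {b.role} {b.sub_label} {b.charge:.17g} "
                f"{b.hard_radius:.17g} {b.mass:.17g} "
                f"{b.position[0]:.17g} {b.position[1]:.17g} {b.position[2]:.17g}\n"
            )
        fh.write(f"[bonds] {len(model.bonds)}\n")
        for t in model.bonds:
            fh.write(f"{t.i} {t.j} {t.k_b:.17g} {t.r_0:.17g}\n")
        fh.write(f"[angles] {len(model.angles)}\n")
        for a in model.angles:
            fh.write(f"{a.i} {a.j} {a.k} {a.k_a:.17g} {a.phi_0:.17g}\n")
        fh.write(f"[groups] {len(model.groups)}\n")
        for name in model.groups:
            idx = " ".join(str(int(i)) for i in model.groups[name])
            fh.write(f"{name} {idx}\n")
        fh.write("[end]\n")
    finally:
        if own:
            fh.close()


def read_topology(path_or_file) -> NCPModel:
    """Read a topology file back into a model (lossless round trip)."""
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    fh = open(path_or_file) if own else path_or_file
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    it = iter(enumerate(lines, start=1))

    def next_line():
        for _, raw in it:
            if raw.strip():
                return raw.strip()
        raise ParseError("unexpected end of topology file (truncated?)")

    if next_line() != TOPOLOGY_MAGIC:
        raise ParseError("not a nucleocg topology file")
    tag, ver = next_line().split()
    if tag != "version" or int(ver) != TOPOLOGY_VERSION:
        raise ParseError(
            f"unsupported topology version {ver} (expected {TOPOLOGY_VERSION})"
        )
    n_beads = int(next_line().split()[1])
    n_ncp = int(next_line().split()[1])
    if next_line() != "[beads]":
        raise ParseError("missing [beads] section")
    beads = []
    for _ in range(n_beads):
        parts = next_line().split()
        beads.append(
            Bead(
                index=int(parts[0]),
                role=parts[1],
                sub_label=parts[2],
                charge=float(parts[3]),
                hard_radius=float(parts[4]),
                mass=float(parts[5]),
                position=np.array([float(x) for x in parts[6:9]]),
            )
        )
    head = next_line().split()
    if head[0] != "[bonds]":
        raise ParseError("missing [bonds] section")
    bonds = []
    for _ in range(int(head[1])):
        i, j, kb, r0 = next_line().split()
        bonds.append(BondTerm(int(i), int(j), float(kb), float(r0)))
    head = next_line().split()
    if head[0] != "[angles]":
        raise ParseError("missing [angles] section")
    angles = []
    for _ in range(int(head[1])):
        i, j, k, ka, phi0 = next_line().split()
        angles.append(AngleTerm(int(i), int(j), int(k), float(ka), float(phi0)))
    head = next_line().split()
    if head[0] != "[groups]":
        raise ParseError("missing [groups] section")
    groups = {}
    for _ in range(int(head[1])):
        parts = next_line().split()
        groups[parts[0]] = np.array([int(x) for x in parts[1:]], dtype=int)
    if next_line() != "[end]":
        raise ParseError("missing [end] marker (truncated file?)")
    return NCPModel(beads=beads, bonds=bonds, angles=angles, groups=groups,
                    n_ncp=n_ncp)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------
@dataclass
class TrajectoryFrame:
    """Positions of every bead at one recorded step."""

    step: int
    box_edge: float
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box_edge <= 0:
            raise ValueError("box_edge must be > 0")


_ROLE_SYMBOL = {"core": "C", "tail": "T", "dna_d": "D", "dna_p": "P", "ion": "X"}


def write_trajectory(frames, path_or_file, roles=None) -> None:
    """Write frames as XYZ-dialect text blocks.

    Each block: bead count, a ``# step N box B`` comment, then one
    ``symbol x y z`` line per bead in fixed order.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("cannot write an empty trajectory")
    n = len(frames[0].positions)
    for f in frames:
        if len(f.positions) != n:
            raise ValueError("inconsistent bead count across frames")
    symbols = (
        [_ROLE_SYMBOL.get(r, "Y") for r in roles] if roles is not None
        else ["Y"] * n
    )
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    fh = open(path_or_file, "w") if own else path_or_file
    try:
        for f in frames:
            fh.write(f"{n}\n")
            fh.write(f"# step {f.step} box {f.box_edge:.10g}\n")
            for s, p in zip(symbols, f.positions):
                fh.write(f"{s} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    finally:
        if own:
            fh.close()


def read_trajectory(path_or_file) -> list[TrajectoryFrame]:
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    fh = open(path_or_file) if own else path_or_file
    try:
        frames = []
        n_expected = None
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline().split()
            if len(comment) < 5 or comment[1] != "step" or comment[3] != "box":
                raise ParseError("malformed trajectory comment line")
            step = int(comment[2])
            box = float(comment[4])
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise ParseError("truncated trajectory frame")
                pos[i] = [float(x) for x in parts[1:4]]
            if n_expected is None:
                n_expected = n
            elif n != n_expected:
                raise ParseError("inconsistent bead count across frames")
            frames.append(TrajectoryFrame(step=step, box_edge=box, positions=pos))
        if not frames:
            raise ParseError("empty trajectory file")
        return frames
    finally:
        if own:
            fh.close()


def roundtrip_topology_string(model: NCPModel) -> NCPModel:
    """Write + read a model through an in-memory buffer (test helper)."""
    buf = io.StringIO()
    write_topology(model, buf)
    buf.seek(0)
    return read_topology(buf)
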