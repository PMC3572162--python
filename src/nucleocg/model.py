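"""Domain types shared across the package.

A coarse-grained nucleosome core particle (NCP) is an ordered collection of
beads (one per amino acid, one per two-bp DNA fragment plus four phosphate
beads, plus mobile ions) held together by harmonic bond and angle terms.
Positions are in Ångström, charges in elementary charges, energies in kT,
masses in reduced units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: allowed bead roles
ROLES = ("core", "tail", "dna_d", "dna_p", "ion")

#: charge states allowed for model (non-ion) beads and for ions
MODEL_CHARGES = (-1.0, 0.0, 1.0)
ION_CHARGES = (1.0, 2.0, 3.0, -1.0)


class ModelError(ValueError):
    """Raised when an NCP model violates one of its structural invariants."""


@dataclass
class Bead:
    """A single coarse-grained particle.

    Parameters
    ----------
    index : int
        Position of the bead in the model's ordered bead list.
    role : str
        One of :data:`ROLES` — histone core, histone tail, DNA central bead
        (D), DNA phosphate (P) or mobile ion.
    sub_label : str
        Histone/tail type (``H2A``, ``H2B``, ``H3``, ``H4``, ``H2A-C``) or
        ion species (``K``, ``Mg``, ``CoHex``, ``Cl``); free-form for DNA.
    charge : float
        Charge in units of e.
    hard_radius : float
        Hard-core radius R_i in Å; the effective radius is R_i + sigma/2.
    mass : float
        Mass in reduced units.
    position : ndarray, shape (3,)
        Coordinates in Å.
    """

    index: int
    role: str
    sub_label: str
    charge: float
    hard_radius: float
    mass: float
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.role not in ROLES:
            raise ModelError(f"unknown bead role {self.role!r}")
        if self.hard_radius < 0:
            raise ModelError("hard_radius must be >= 0")
        if self.mass <= 0:
            raise ModelError("mass must be > 0")
        allowed = ION_CHARGES if self.role == "ion" else MODEL_CHARGES
        if self.charge not in allowed:
            raise ModelError(
                f"charge {self.charge} not allowed for role {self.role!r}"
            )


@dataclass
class BondTerm:
    """Harmonic bond U(r) = (k_b/2)(r - r_0)^2, k_b in kT/Å², r_0 in Å."""

    i: int
    j: int
    k_b: float
    r_0: float

    def __post_init__(self):
        if self.i == self.j:
            raise ModelError("bond endpoints must differ")
        if self.k_b <= 0 or self.r_0 <= 0:
            raise ModelError("bond force constant and length must be > 0")


@dataclass
class AngleTerm:
    """Harmonic angle U(phi) = (k_a/2)(phi - phi_0)^2 with vertex j.

    phi_0 in radians, k_a in kT/rad².
    """

    i: int
    j: int
    k: int
    k_a: float
    phi_0: float

    def __post_init__(self):
        if len({self.i, self.j, self.k}) != 3:
            raise ModelError("angle needs three distinct bead indices")
        if not 0.0 < self.phi_0 <= np.pi + 1e-12:
            raise ModelError("equilibrium angle must be in (0, pi]")
        if self.k_a <= 0:
            raise ModelError("angle force constant must be > 0")


@dataclass
class NCPModel:
    """Beads + bonded terms + named index groups for one or more NCPs.

    Group naming: for a single NCP the canonical groups are ``core``,
    ``tails_all``, ``tail_<type>_<copy>``, ``dna_D``, ``dna_P``,
    ``dna_strand1``, ``dna_strand2``, ``dyad_sites`` (2 beads defining the
    dyad axis), ``frame_sites`` (3 well-separated core beads for the SDF
    local frame) and ``axis_sites`` (2 beads near the superhelix axis ends).
    Multi-NCP systems prefix each with ``ncp<i>/``; appended mobile ions go
    into ``ions`` and ``ions_<species>``.
    """

    beads: list[Bead]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    n_ncp: int = 1

    # ------------------------------------------------------------------
    # array views
    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (self.n_beads, 3):
            raise ModelError("position array shape mismatch")
        for b, p in zip(self.beads, pos):
            b.position = p.copy()

    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads], dtype=float)

    def hard_radii(self) -> np.ndarray:
        return np.array([b.hard_radius for b in self.beads], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads], dtype=float)

    def roles(self) -> list[str]:
        return [b.role for b in self.beads]

    def net_charge(self) -> float:
        return float(sum(b.charge for b in self.beads))

    def group(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.groups[name], dtype=int)
        except KeyError:
            raise KeyError(
                f"model has no group {name!r}; available: {sorted(self.groups)}"
            ) from None

    def select_role(self, role: str) -> np.ndarray:
        return np.array(
            [b.index for b in self.beads if b.role == role], dtype=int
        )

    # ------------------------------------------------------------------
    # invariants
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants of a single assembled NCP.

        Raises :class:`ModelError` listing every failed check. Only
        meaningful for ``n_ncp == 1`` models without appended ions.
        """
        problems: list[str] = []
        n_ions = sum(1 for b in self.beads if b.role == "ion")
        counts = {r: 0 for r in ROLES}
        for b in self.beads:
            counts[b.role] += 1
        if self.n_ncp == 1 and n_ions == 0:
            if counts["core"] != 710:
                problems.append(f"core bead count {counts['core']} != 710")
            if counts["tail"] != 270:
                problems.append(f"tail bead count {counts['tail']} != 270")
            n_dna = counts["dna_d"] + counts["dna_p"]
            if n_dna != 370:
                problems.append(f"DNA bead count {n_dna} != 370")
            if self.n_beads != 1350:
                problems.append(f"total bead count {self.n_beads} != 1350")
            q = self.net_charge()
            if abs(q - (-150.0)) > 1e-9:
                problems.append(f"net charge {q} != -150e")
        for idx, b in enumerate(self.beads):
            if b.index != idx:
                problems.append("bead indices not consecutive from 0")
                break
        # every tail is a simple chain anchored at exactly one end
        problems += self._check_tail_chains()
        # every D bead carries exactly one link bond to a core bead
        d_idx = set(self.select_role("dna_d").tolist())
        core_idx = set(self.select_role("core").tolist())
        if d_idx:
            links = {i: 0 for i in d_idx}
            for bd in self.bonds:
                if bd.i in d_idx and bd.j in core_idx:
                    links[bd.i] += 1
                elif bd.j in d_idx and bd.i in core_idx:
                    links[bd.j] += 1
            bad = [i for i, c in links.items() if c != 1]
            if bad:
                problems.append(
                    f"{len(bad)} D beads without exactly one core link bond"
                )
        if problems:
            raise ModelError("model invariant violations: " + "; ".join(problems))

    def _check_tail_chains(self) -> list[str]:
        problems = []
        tail_groups = [
            g for g in self.groups if g.split("/")[-1].startswith("tail_")
        ]
        core_idx = set(self.select_role("core").tolist())
        for g in tail_groups:
            idx = list(self.group(g))
            members = set(idx)
            deg_in = {i: 0 for i in idx}
            anchors = 0
            for bd in self.bonds:
                if bd.i in members and bd.j in members:
                    deg_in[bd.i] += 1
                    deg_in[bd.j] += 1
                elif bd.i in members and bd.j in core_idx:
                    anchors += 1
                elif bd.j in members and bd.i in core_idx:
                    anchors += 1
            if anchors != 1:
                problems.append(f"group {g}: {anchors} core anchors (want 1)")
            ends = sum(1 for d in deg_in.values() if d == 1)
            mids = sum(1 for d in deg_in.values() if d == 2)
            if len(idx) > 1 and not (ends == 2 and mids == len(idx) - 2):
                problems.append(f"group {g}: not a simple chain")
        return problems

    # structural comparison used by tests and round-trip checks ---------
    def equals(self, other: "NCPModel", pos_rtol: float = 1e-6) -> bool:
        if self.n_beads != other.n_beads or self.n_ncp != other.n_ncp:
            return False
        for a, b in zip(self.beads, other.beads):
            if (a.role, a.sub_label, a.charge, a.hard_radius, a.mass) != (
                b.role,
                b.sub_label,
                b.charge,
                b.hard_radius,
                b.mass,
            ):
                return False
            if not np.allclose(a.position, b.position, rtol=pos_rtol, atol=1e-5):
                return False
        if [(t.i, t.j, t.k_b, t.r_0) for t in self.bonds] != [
            (t.i, t.j, t.k_b, t.r_0) for t in other.bonds
        ]:
            return False
        if len(self.angles) != len(other.angles):
            return False
        for a, b in zip(self.angles, other.angles):
            if (a.i, a.j, a.k, a.k_a) != (b.i, b.j, b.k, b.k_a):
                return False
            if abs(a.phi_0 - b.phi_0) > 1e-9:
                return False
        if set(self.groups) != set(other.groups):
            return False
        return all(
            np.array_equal(self.group(g), other.group(g)) for g in self.groups
        )
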