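"""Interaction model: continuum-dielectric Coulomb, purely repulsive
(WCA-style) Lennard-Jones on the hard-core-shifted distance, and harmonic
bond/angle terms.

Energies are in kT (kT = 1 is the energy unit); temperature enters only
through the Bjerrum length, which converts charge products to kT at the
chosen relative permittivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants as sc

from . import _kernels
from .model import NCPModel

TWO_SIXTH = 2.0 ** (1.0 / 6.0)

DEFAULT_ION_HARD_RADII = {"K": 0.0, "Mg": 0.5, "CoHex": 1.5, "Cl": 0.0}


class ForceFieldError(ValueError):
    pass


class HardCoreOverlapWarning(UserWarning):
    """Beads found inside each other's hard core (energy was capped)."""


def bjerrum_length(epsilon_r: float = 78.0, temperature_K: float = 298.0) -> float:
    """Distance (Å) at which two unit charges interact with energy kT."""
    lb_m = sc.e**2 / (
        4.0 * np.pi * sc.epsilon_0 * epsilon_r * sc.k * temperature_K
    )
    return lb_m * 1e10


@dataclass
class ForceFieldParams:
    """Non-bonded parameters.

    epsilon_r : relative permittivity of the implicit solvent (78).
    sigma : soft Lennard-Jones length, Å (4; soft radius sigma/2 per bead).
    epsilon_lj : repulsion strength, kT (1).
    ion_hard_radii : hard-core radius per ion species, Å.
    temperature_K : temperature used for the Bjerrum-length conversion.
    coulomb_excludes_bonded : drop directly bonded (1-2) pairs from the
        Coulomb sum (off by default: most bonded neighbours are neutral and
        periodic mesh methods include all pairs anyway).
    wca_excludes_bonded : drop 1-2 pairs from the short-range repulsion
        (on by default: several equilibrium bond lengths lie below contact).
    overlap_cap_kt : energy at which the repulsion switches to a linear
        ramp, keeping forces finite for overlapping beads.
    """

    epsilon_r: float = 78.0
    sigma: float = 4.0
    epsilon_lj: float = 1.0
    ion_hard_radii: dict = field(
        default_factory=lambda: dict(DEFAULT_ION_HARD_RADII)
    )
    temperature_K: float = 298.0
    coulomb_excludes_bonded: bool = False
    wca_excludes_bonded: bool = True
    overlap_cap_kt: float = 100.0

    def __post_init__(self):
        if self.epsilon_r <= 0 or self.sigma <= 0 or self.epsilon_lj <= 0:
            raise ForceFieldError("epsilon_r, sigma and epsilon_lj must be > 0")

    @property
    def bjerrum(self) -> float:
        return bjerrum_length(self.epsilon_r, self.temperature_K)

    @property
    def wca_cutoff_x(self) -> float:
        return TWO_SIXTH * self.sigma

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        """Read ``key = value`` overrides of the defaults from a text file."""
        params = cls()
        floats = {
            "epsilon_r", "sigma", "epsilon_lj", "temperature_K",
            "overlap_cap_kt",
        }
        bools = {"coulomb_excludes_bonded", "wca_excludes_bonded"}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key in floats:
                    params = replace(params, **{key: float(val)})
                elif key in bools:
                    params = replace(
                        params, **{key: val.lower() in ("1", "true", "yes")}
                    )
                elif key.startswith("hard_radius_"):
                    params.ion_hard_radii[key[len("hard_radius_"):]] = float(val)
                else:
                    raise ForceFieldError(f"unknown parameter {key!r}")
        return params


# ---------------------------------------------------------------------------
# scalar pair terms (reference implementations; kernels mirror these)
# ---------------------------------------------------------------------------
def coulomb_energy(q_i: float, q_j: float, r: float,
                   params: ForceFieldParams) -> float:
    """U = l_B q_i q_j / r in kT."""
    if r <= 0:
        raise ForceFieldError(f"coulomb_energy needs r > 0, got {r}")
    return params.bjerrum * q_i * q_j / r


def lj_repulsive_energy(r: float, R_i: float, R_j: float,
                        params: ForceFieldParams) -> float:
    """WCA repulsion on x = r - (R_i + R_j); capped inside the hard core.

    For x in (0, 2^(1/6) sigma): U = 4 eps [(sigma/x)^12 - (sigma/x)^6] + eps;
    zero beyond the cutoff. At r <= R_i + R_j (hard-core overlap) the energy
    continues on the finite linear cap used by the integrator.
    """
    rij = R_i + R_j
    x = r - rij
    sigma, eps = params.sigma, params.epsilon_lj
    if x >= TWO_SIXTH * sigma:
        return 0.0
    ycap = (1.0 + np.sqrt(params.overlap_cap_kt)) / 2.0
    xcap = sigma * ycap ** (-1.0 / 6.0)
    if x <= xcap:
        fcap = 4.0 * eps * (12.0 * ycap**2 - 6.0 * ycap) / xcap
        return params.overlap_cap_kt * eps + fcap * (xcap - x)
    s6 = (sigma / x) ** 6
    return 4.0 * eps * (s6 * s6 - s6) + eps


def bond_energy(r: float, k_b: float, r_0: float) -> float:
    """U = (k_b/2)(r - r_0)^2 in kT."""
    if r <= 0:
        raise ForceFieldError("bond_energy needs r > 0")
    return 0.5 * k_b * (r - r_0) ** 2


def angle_energy(phi: float, k_a: float, phi_0: float) -> float:
    """U = (k_a/2)(phi - phi_0)^2 in kT, phi in radians."""
    if not 0.0 <= phi <= np.pi + 1e-12:
        raise ForceFieldError("angle must lie in [0, pi]")
    return 0.5 * k_a * (phi - phi_0) ** 2


# ---------------------------------------------------------------------------
# whole-system evaluation
# ---------------------------------------------------------------------------
class ForceTables:
    """Flat array view of a model's interaction terms, kernel-ready."""

    def __init__(self, model: NCPModel, params: ForceFieldParams):
        self.params = params
        n = model.n_beads
        self.n = n
        self.charges = model.charges()
        self.radii = model.hard_radii()
        self.masses = model.masses()
        self.bond_i = np.array([b.i for b in model.bonds], dtype=np.int64)
        self.bond_j = np.array([b.j for b in model.bonds], dtype=np.int64)
        self.bond_k = np.array([b.k_b for b in model.bonds], dtype=float)
        self.bond_r0 = np.array([b.r_0 for b in model.bonds], dtype=float)
        self.ang_i = np.array([a.i for a in model.angles], dtype=np.int64)
        self.ang_j = np.array([a.j for a in model.angles], dtype=np.int64)
        self.ang_k = np.array([a.k for a in model.angles], dtype=np.int64)
        self.ang_ka = np.array([a.k_a for a in model.angles], dtype=float)
        self.ang_phi0 = np.array([a.phi_0 for a in model.angles], dtype=float)
        lo = np.minimum(self.bond_i, self.bond_j)
        hi = np.maximum(self.bond_i, self.bond_j)
        keys = np.unique(lo.astype(np.int64) * n + hi)
        self.wca_excl = keys if params.wca_excludes_bonded else np.empty(
            0, dtype=np.int64
        )
        # bonded pairs with both partners charged (Coulomb exclusion option)
        qmask = (self.charges[lo] != 0) & (self.charges[hi] != 0) if len(lo) \
            else np.zeros(0, dtype=bool)
        self.coul_excl_i = lo[qmask]
        self.coul_excl_j = hi[qmask]
        self.charged = np.flatnonzero(self.charges != 0.0)
        rmax = self.radii.max(initial=0.0)
        self.wca_rlist = 2.0 * rmax + params.wca_cutoff_x

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


def total_energy_forces(
    positions: np.ndarray,
    tables: ForceTables,
    box_edge: float | None = None,
    electrostatics: str = "direct",
    pair_list: tuple[np.ndarray, np.ndarray] | None = None,
    neighbor_skin: float = 2.0,
    ewald_accuracy: float = 1e-4,
    return_terms: bool = False,
):
    """Total potential energy (kT) and per-bead forces (kT/Å).

    electrostatics : 'direct' (minimum-image bare Coulomb; the exact
        non-periodic sum when box_edge is None), 'ewald'/'mesh' (classic
        Ewald summation, requires a neutral periodic system) or 'none'.
    pair_list : optional precomputed WCA pair list; built on the fly if
        missing.
    """
    if hasattr(positions, "positions"):  # a SystemState
        if box_edge is None:
            box_edge = positions.box_edge
        positions = positions.positions
    if isinstance(tables, NCPModel):
        tables = ForceTables(tables, ForceFieldParams())
    pos = np.ascontiguousarray(positions, dtype=float)
    n = pos.shape[0]
    if n != tables.n:
        raise ForceFieldError("position count does not match model")
    box = float(box_edge) if box_edge else -1.0
    params = tables.params
    forces = np.zeros_like(pos)
    terms: dict[str, float] = {}

    e_bond = _kernels.bond_ef(
        pos, tables.bond_i, tables.bond_j, tables.bond_k, tables.bond_r0,
        box, forces,
    ) if len(tables.bond_i) else 0.0
    e_ang = _kernels.angle_ef(
        pos, tables.ang_i, tables.ang_j, tables.ang_k, tables.ang_ka,
        tables.ang_phi0, box, forces,
    ) if len(tables.ang_i) else 0.0

    if pair_list is None:
        pair_list = _kernels.build_pair_list(
            pos, box, tables.wca_rlist + neighbor_skin, tables.wca_excl
        )
    e_wca, n_overlap = _kernels.wca_pairs_ef(
        pos, pair_list[0], pair_list[1], tables.radii, box,
        params.sigma, params.epsilon_lj, params.overlap_cap_kt, forces,
    )

    e_coul = 0.0
    method = electrostatics.lower()
    if method in ("mesh", "ewald"):
        method = "ewald"
    if method not in ("direct", "ewald", "none"):
        raise ForceFieldError(f"unknown electrostatics method {electrostatics!r}")
    idx = tables.charged
    if method != "none" and len(idx) > 1:
        sub = np.ascontiguousarray(pos[idx])
        qsub = np.ascontiguousarray(tables.charges[idx])
        fsub = np.zeros_like(sub)
        if method == "direct":
            e_coul = _kernels.coulomb_direct_ef(
                sub, qsub, params.bjerrum, box, fsub
            )
        else:
            if box <= 0:
                raise ForceFieldError("ewald electrostatics requires a box")
            if abs(qsub.sum()) > 1e-9:
                raise ForceFieldError(
                    "ewald electrostatics requires a neutral system "
                    f"(net charge {qsub.sum():g}e)"
                )
            e_coul = _ewald(sub, qsub, params.bjerrum, box, ewald_accuracy, fsub)
        forces[idx] += fsub
        if params.coulomb_excludes_bonded and len(tables.coul_excl_i):
            e_coul += _kernels.coulomb_pairs_ef(
                pos, tables.coul_excl_i, tables.coul_excl_j, tables.charges,
                params.bjerrum, box, -1.0, forces,
            )

    energy = e_bond + e_ang + e_wca + e_coul
    if not np.isfinite(energy) or not np.all(np.isfinite(forces)):
        bad = np.flatnonzero(~np.isfinite(forces).all(axis=1))
        raise ForceFieldError(
            "non-finite energy/forces "
            f"(energy={energy}, first bad beads {bad[:5].tolist()})"
        )
    if return_terms:
        terms = {
            "bond": e_bond, "angle": e_ang, "wca": e_wca,
            "coulomb": e_coul, "n_overlap": float(n_overlap),
        }
        return energy, forces, terms
    return energy, forces


def ewald_parameters(box: float, accuracy: float) -> tuple[float, float, np.ndarray]:
    """(alpha, r_cut, k-vectors) for the requested relative accuracy."""
    s = max(np.sqrt(-np.log(accuracy)), 2.0)  # erfc(s) ~ accuracy
    rcut = box / 2.0 * 0.999
    alpha = s / rcut
    nmax = int(np.ceil(s * box * alpha / np.pi))
    rng = np.arange(-nmax, nmax + 1)
    nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
    nvec = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
    nvec = nvec[np.any(nvec != 0, axis=1)]
    k2 = (nvec**2).sum(axis=1) * (2 * np.pi / box) ** 2
    keep = k2 <= (2.0 * alpha * s) ** 2
    kvecs = nvec[keep] * (2 * np.pi / box)
    return alpha, rcut, np.ascontiguousarray(kvecs, dtype=float)


def _ewald(pos, q, lb, box, accuracy, forces):
    alpha, rcut, kvecs = ewald_parameters(box, accuracy)
    e = _kernels.ewald_real_ef(pos, q, lb, box, alpha, rcut, forces)
    e += _kernels.ewald_recip_ef(pos, q, lb, box, alpha, kvecs, forces)
    e -= lb * alpha / np.sqrt(np.pi) * float((q**2).sum())
    return e
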