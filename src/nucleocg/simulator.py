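"""Langevin dynamics of NCPs with explicit counterions in a periodic box.

The equation of motion per bead is

    m dv/dt = F_conservative - gamma * v + xi(t)

with the random force amplitude fixed by the fluctuation-dissipation
theorem at the target kT. Integration uses a BAOAB splitting of velocity
Verlet (exact Ornstein-Uhlenbeck velocity update), which reduces to plain
velocity Verlet at gamma = 0. kT = 1 and masses are reduced units; the
friction is deliberately weak (gamma = 0.01) since only equilibrium
averages are of interest and low friction samples configuration space
faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from . import constants as C
from .forcefield import ForceFieldParams, ForceTables, total_energy_forces
from .model import Bead, NCPModel
from .structure_io import TrajectoryFrame


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationParams:
    """Integration and electrostatics settings (reduced units).

    dt: time step (0.01); gamma: thermostat friction (0.01); kT: 1;
    box_edge in Å (400 Å = 40 nm cell); electrostatics 'direct' or
    'ewald'/'mesh'; mesh_accuracy: target relative force error of the
    Ewald sum; neighbor_skin: Verlet-list skin in Å.
    """

    n_steps: int = 10_000
    dt: float = 0.01
    gamma: float = 0.01
    kT: float = 1.0
    box_edge: float = 400.0
    seed: int = 0
    electrostatics: str = "direct"
    mesh_accuracy: float = 1e-4
    neighbor_skin: float = 2.0
    traj_stride: int = 1000
    max_step_displacement: float = 10.0  # Å; abort beyond this

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be > 0")


@dataclass
class SystemState:
    """Positions/velocities plus the bookkeeping needed to continue a run."""

    positions: np.ndarray
    velocities: np.ndarray
    box_edge: float
    step: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")


@dataclass
class Trajectory:
    frames: list[TrajectoryFrame] = field(default_factory=list)

    def __len__(self):
        return len(self.frames)

    def positions(self) -> np.ndarray:
        return np.stack([f.positions for f in self.frames])


def initial_state(
    model: NCPModel, params: SimulationParams, seed: int | None = None
) -> SystemState:
    """Model positions plus Maxwell-Boltzmann velocities at kT."""
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    masses = model.masses()
    vel = rng.standard_normal((model.n_beads, 3)) * np.sqrt(
        params.kT / masses
    )[:, None]
    return SystemState(
        positions=model.positions(),
        velocities=vel,
        box_edge=params.box_edge,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# counterions
# ---------------------------------------------------------------------------
def place_counterions(
    model: NCPModel,
    species: str,
    box_edge: float,
    seed: int = 0,
    n_salt_pairs: int = 0,
    salt_species: tuple[str, str] = ("K", "Cl"),
    ff_params: ForceFieldParams | None = None,
    max_tries_per_ion: int = 2000,
) -> NCPModel:
    """Append neutralizing counterions (and optional added-salt pairs).

    The counterion count is the total NCP charge magnitude divided by the
    ion valence (exact electroneutrality; a non-divisible charge is an
    error). Positions are uniform random in the box, rejected while any
    existing bead lies within the contact distance R_i + R_j + sigma.
    Deterministic per seed.
    """
    if species not in C.ION_SPECIES or species == "Cl":
        raise SimulationError(f"unknown counterion species {species!r}")
    params = ff_params or ForceFieldParams()
    valence, radius = C.ION_SPECIES[species]
    net = model.net_charge()
    n_ions_f = -net / valence
    n_ions = int(round(n_ions_f))
    if n_ions < 0 or abs(n_ions_f - n_ions) > 1e-9:
        raise SimulationError(
            f"NCP charge {net}e is not neutralized by an integer number of "
            f"{species}{valence:+d} ions"
        )
    rng = np.random.default_rng(seed)
    to_place = [(species, valence, radius)] * n_ions
    for sp in salt_species * n_salt_pairs:
        v, r = C.ION_SPECIES[sp]
        to_place.append((sp, v, r))
    existing = model.positions()
    radii = list(model.hard_radii())
    beads = list(model.beads)
    new_idx_by_species: dict[str, list[int]] = {}
    placed: list[np.ndarray] = []
    for sp, v, r in to_place:
        ok = False
        for _ in range(max_tries_per_ion):
            cand = rng.random(3) * box_edge
            d = existing - cand
            d -= box_edge * np.round(d / box_edge)
            dist = np.sqrt((d**2).sum(axis=1))
            if (dist < np.asarray(radii) + r + params.sigma).any():
                continue
            ok = True
            break
        if not ok:
            raise SimulationError(
                f"failed to place {sp} ion without overlap after "
                f"{max_tries_per_ion} tries"
            )
        idx = len(beads)
        beads.append(
            Bead(idx, "ion", sp, float(v), r, 1.0, cand)
        )
        existing = np.vstack([existing, cand])
        radii.append(r)
        placed.append(cand)
        new_idx_by_species.setdefault(sp, []).append(idx)
    groups = {k: np.asarray(v).copy() for k, v in model.groups.items()}
    all_ions = sorted(i for v in new_idx_by_species.values() for i in v)
    groups["ions"] = np.array(all_ions, dtype=int)
    for sp, idx in new_idx_by_species.items():
        groups[f"ions_{sp}"] = np.array(sorted(idx), dtype=int)
    out = NCPModel(
        beads=beads,
        bonds=list(model.bonds),
        angles=list(model.angles),
        groups=groups,
        n_ncp=model.n_ncp,
    )
    if abs(out.net_charge()) > 1e-9 and n_salt_pairs == 0:
        raise SimulationError("system not neutral after ion placement")
    return out


# ---------------------------------------------------------------------------
# electrostatics entry point (spec surface; delegates to forcefield)
# ---------------------------------------------------------------------------
def electrostatic_energy_forces(
    state: SystemState,
    charges: np.ndarray,
    method: str = "ewald",
    accuracy: float = 1e-4,
):
    """Periodic electrostatic energy/forces of point charges in the box."""
    from .forcefield import ewald_parameters, _ewald, ForceFieldError

    q = np.ascontiguousarray(charges, dtype=float)
    pos = np.ascontiguousarray(state.positions)
    lb = ForceFieldParams().bjerrum
    forces = np.zeros_like(pos)
    method = method.lower()
    if method in ("ewald", "mesh"):
        if abs(q.sum()) > 1e-9:
            raise SimulationError(
                f"periodic mesh electrostatics requires a neutral system "
                f"(net charge {q.sum():g}e)"
            )
        e = _ewald(pos, q, lb, state.box_edge, accuracy, forces)
    elif method == "direct":
        e = _kernels.coulomb_direct_ef(pos, q, lb, state.box_edge, forces)
    else:
        raise SimulationError(f"unknown electrostatics method {method!r}")
    return e, forces


# ---------------------------------------------------------------------------
# energy minimization (steepest descent with capped step)
# ---------------------------------------------------------------------------
def minimize(
    state: SystemState,
    tables: ForceTables,
    sim_params: SimulationParams,
    n_steps: int = 200,
    max_move: float = 0.2,
) -> float:
    """Relax overlaps before dynamics; returns the final energy."""
    pos = state.positions
    energy = np.inf
    for _ in range(n_steps):
        energy, forces = total_energy_forces(
            pos, tables, state.box_edge, sim_params.electrostatics,
            neighbor_skin=sim_params.neighbor_skin,
            ewald_accuracy=sim_params.mesh_accuracy,
        )
        fmax = np.abs(forces).max()
        if fmax < 1e-3:
            break
        pos += forces * min(max_move / fmax, 0.05)
    state.positions = pos
    return float(energy)


# ---------------------------------------------------------------------------
# the integrator
# ---------------------------------------------------------------------------
def run(
    state: SystemState,
    model: NCPModel,
    ff_params: ForceFieldParams,
    sim_params: SimulationParams,
    reporters: tuple = (),
    tables: ForceTables | None = None,
) -> Trajectory:
    """Integrate Langevin dynamics; bit-reproducible for a fixed seed.

    Frames (including the final state) are recorded every
    ``sim_params.traj_stride`` steps and passed to each reporter as
    ``reporter(frame, kinetic_temperature, potential_energy)``.
    """
    tables = tables or ForceTables(model, ff_params)
    pos = state.positions
    vel = state.velocities
    if pos.shape[0] != tables.n:
        raise SimulationError("state bead count does not match model")
    box = state.box_edge
    dt = sim_params.dt
    m = tables.masses[:, None]
    c1 = np.exp(-sim_params.gamma * dt / m)
    c2 = np.sqrt(sim_params.kT * (1.0 - c1**2) / m)
    rng = state.rng
    ndof = 3 * pos.shape[0]

    skin = sim_params.neighbor_skin
    rlist = tables.wca_rlist + skin
    ref_pos = pos.copy()
    pairs = _kernels.build_pair_list(pos, box, rlist, tables.wca_excl)

    def forces_at(p):
        return total_energy_forces(
            p, tables, box, sim_params.electrostatics, pair_list=pairs,
            ewald_accuracy=sim_params.mesh_accuracy,
        )

    energy, forces = forces_at(pos)
    traj = Trajectory()

    def record(step):
        frame = TrajectoryFrame(step=step, box_edge=box, positions=pos.copy())
        traj.frames.append(frame)
        kin_t = float((m * vel**2).sum() / ndof)
        for rep in reporters:
            rep(frame, kin_t, energy)

    half = 0.5 * dt
    for step_i in range(sim_params.n_steps):
        vel += half * forces / m
        pos += half * vel
        if sim_params.gamma > 0:
            vel *= c1
            vel += c2 * rng.standard_normal(pos.shape)
        pos += half * vel
        # neighbour-list validity: rebuild once any bead moved half a skin
        disp2 = ((pos - ref_pos) ** 2).sum(axis=1).max()
        if disp2 > (0.5 * skin) ** 2:
            max_move = np.sqrt(disp2)
            if max_move > sim_params.max_step_displacement:
                raise SimulationError(
                    f"bead moved {max_move:.1f} Å within one neighbour-list "
                    f"period at step {state.step + step_i}: unstable dynamics"
                )
            pairs = _kernels.build_pair_list(pos, box, rlist, tables.wca_excl)
            ref_pos = pos.copy()
        energy, forces = forces_at(pos)
        vel += half * forces / m
        state.step += 1
        if (step_i + 1) % sim_params.traj_stride == 0:
            record(state.step)
    if sim_params.n_steps % sim_params.traj_stride != 0:
        record(state.step)
    state.positions = pos
    state.velocities = vel
    return traj


def equilibration_split(traj: Trajectory, fraction: float = 0.4):
    """Discard the leading ``fraction`` of frames as equilibration.

    Mirrors the production protocol where the initial 40% of steps
    (10^9 of 2.5x10^9) were disregarded. Returns (discarded, production).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n = len(traj.frames)
    k = int(round(n * fraction))
    return (
        Trajectory(frames=traj.frames[:k]),
        Trajectory(frames=traj.frames[k:]),
    )
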