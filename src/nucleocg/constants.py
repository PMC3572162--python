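"""Model constants: charge rules, tail definitions, DNA geometry, masses.

Versioned so that topology files can record which constant set built them.
"""

from __future__ import annotations

import numpy as np

CONSTANTS_VERSION = 1

# ---------------------------------------------------------------------------
# amino-acid charge rule: Lys/Arg +1e, Asp/Glu -1e, all other standard
# residues neutral.
# ---------------------------------------------------------------------------
POSITIVE_RESIDUES = {"LYS", "ARG"}
NEGATIVE_RESIDUES = {"ASP", "GLU"}
NEUTRAL_RESIDUES = {
    "ALA", "ASN", "CYS", "GLN", "GLY", "HIS", "ILE", "LEU", "MET", "PHE",
    "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
AMINO_ACIDS = POSITIVE_RESIDUES | NEGATIVE_RESIDUES | NEUTRAL_RESIDUES

THREE_FROM_ONE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

NUCLEOTIDE_NAMES = {"DA", "DT", "DG", "DC", "A", "T", "G", "C", "U", "DU"}

# ---------------------------------------------------------------------------
# histone tails
#
# Ten tails per octamer: two copies each of the H2A N-tail, H2B, H3, H4 and
# the short H2A C-tail, with bead counts 20/35/43/24/13. Sequences are the
# canonical histone termini (one-letter), except the H2A C-tail 13-mer which
# is a synthetic stand-in constructed so that the ten tails together carry
# the octamer-tail net charge of +94e.
# ---------------------------------------------------------------------------
TAIL_TYPES = ("H2A", "H2B", "H3", "H4", "H2A-C")

TAIL_SEQUENCES_1L = {
    "H2A": "SGRGKQGGKARAKAKTRSSR",                      # 20 aa, net +8
    "H2B": "PEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKE",       # 35 aa, net +12
    "H3": "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRP",  # 43 aa, net +14
    "H4": "SGRGKGGKGLGKGGAKRHRKVLRD",                   # 24 aa, net +8
    "H2A-C": "KTESHHKAKGKKK",                           # 13 aa, net +5 (synthetic)
}

TAIL_LENGTHS = {t: len(s) for t, s in TAIL_SEQUENCES_1L.items()}
assert tuple(TAIL_LENGTHS[t] for t in TAIL_TYPES) == (20, 35, 43, 24, 13)

TAIL_SEQUENCES = {
    t: [THREE_FROM_ONE[c] for c in s] for t, s in TAIL_SEQUENCES_1L.items()
}

#: residue ranges (inclusive, deposited numbering) split off each 1KX5
#: histone chain as flexible tails; the rest of the chain is globular core.
TAIL_RANGES = {
    "H3": (("H3", 1, 43),),
    "H4": (("H4", 1, 24),),
    "H2B": (("H2B", 1, 35),),
    "H2A": (("H2A", 1, 20), ("H2A-C", 116, 128)),
}

#: chain id -> histone type for the 1KX5 deposition layout
CHAIN_MAP_1KX5 = {
    "A": "H3", "E": "H3",
    "B": "H4", "F": "H4",
    "C": "H2A", "G": "H2A",
    "D": "H2B", "H": "H2B",
    "I": "DNA", "J": "DNA",
}

# expected composition of one NCP
N_CORE_BEADS = 710
CORE_CHARGE_COUNTS = (116, 64, 530)   # positive / negative / neutral
CORE_NET_CHARGE = 52.0
N_TAIL_BEADS = 270
TAIL_NET_CHARGE = 94.0
N_DNA_UNITS = 74
N_DNA_BEADS = 5 * N_DNA_UNITS
DNA_NET_CHARGE = -4.0 * N_DNA_UNITS
NCP_NET_CHARGE = CORE_NET_CHARGE + TAIL_NET_CHARGE + DNA_NET_CHARGE  # -150
N_NCP_BEADS = N_CORE_BEADS + N_TAIL_BEADS + N_DNA_BEADS              # 1350

# ---------------------------------------------------------------------------
# bonded parameters
# ---------------------------------------------------------------------------
CORE_BOND_K = 5.0          # kT/Å², elastic network
CORE_NEIGHBOURS = 3        # harmonic bonds to the 3 nearest beads
TAIL_BOND_K = 5.0          # kT/Å²
TAIL_BOND_R0 = 3.25        # Å, peptide contour length per residue
LINK_BOND_K = 5.0          # kT/Å², DNA D bead to nearest core bead
TAIL_CHARGED_RADIUS = 0.6  # Å hard radius for charged tail beads

# DNA five-bead unit (two base pairs): one central D bead + four phosphates
DNA_RISE = 3.4             # Å per bp
DNA_DD_SPACING = 6.8       # Å between consecutive D beads (2 bp)
DNA_TWIST_PER_UNIT = 72.0  # degrees of phosphate twist per unit (36°/bp)
DNA_P_CHARGE = -1.0
DNA_P_HARD_RADIUS = 1.0    # Å
DNA_D_HARD_RADIUS = 4.0    # Å
DNA_D_MASS = 4.0           # reduced units; all other beads have mass 1
DNA_CROSS_STRAND_PP = 18.2  # Å, opposite phosphates of the same bp (ideal B)

# bond/angle table of the DNA unit (equilibrium value, force constant)
DNA_BOND_DP = (9.62, 25.0)
DNA_BOND_DD = (6.8, 25.0)
DNA_BOND_PP_STRAND = (6.75, 25.0)
DNA_BOND_PP_MINOR = (13.2, 5.0)
DNA_ANGLE_DDD = (180.0, 50.0)      # degrees, kT/rad²
DNA_ANGLE_STRAND = (149.0, 100.0)
DNA_ANGLE_PDP = (140.0, 100.0)

# constructive phosphate helix geometry (see ncp_builder for derivation):
# radius fixed by the same-strand P-P bond, strand phase by the ideal-B
# cross-strand distance.
DNA_P_RADIUS = _rho = float(
    np.sqrt(DNA_BOND_PP_STRAND[0] ** 2 - DNA_RISE**2)
    / (2.0 * np.sin(np.deg2rad(DNA_TWIST_PER_UNIT / 4.0)))
)
DNA_STRAND_PHASE = float(
    -2.0 * np.degrees(np.arcsin(DNA_CROSS_STRAND_PP / (2.0 * _rho)))
)

# nucleosomal superhelix: 1.75 left-handed turns; radius chosen so that
# consecutive D beads sit 6.8 Å apart at the canonical 23.9 Å pitch.
SUPERHELIX_TURNS = 1.75
SUPERHELIX_PITCH = 23.9    # Å

# mobile ions: species -> (valence, hard radius Å)
ION_SPECIES = {
    "K": (1, 0.0),
    "Mg": (2, 0.5),
    "CoHex": (3, 1.5),
    "Cl": (-1, 0.0),
}

# synthetic core generator (octamer-sized wedge cylinder)
SYNTH_CORE_RADIUS = 30.0   # Å
SYNTH_CORE_HEIGHT_MAX = 57.0
SYNTH_CORE_HEIGHT_MIN = 45.0  # wedge: height tapers with azimuth
SYNTH_CORE_MIN_SPACING = 4.0  # Å minimum bead separation


def superhelix_radius(
    n_units: int = N_DNA_UNITS,
    turns: float = SUPERHELIX_TURNS,
    pitch: float = SUPERHELIX_PITCH,
    dd: float = DNA_DD_SPACING,
) -> float:
    """Radius at which consecutive D-bead chords equal ``dd``."""
    dtheta = 2.0 * np.pi * turns / (n_units - 1)
    c = pitch / (2.0 * np.pi)
    chord_xy = np.sqrt(dd**2 - (c * dtheta) ** 2)
    return float(chord_xy / (2.0 * np.sin(dtheta / 2.0)))
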