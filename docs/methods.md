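# Methods

`nucleocg` implements a bead-resolution coarse-grained model of the
nucleosome core particle (NCP) — the 147-bp DNA/histone-octamer complex
that is the repeating unit of chromatin — together with the Langevin
dynamics and analysis machinery needed to study how mobile counterions of
different valence modulate NCP structure and NCP–NCP interactions.

## The model

**Particles.** One NCP comprises 1350 beads:

* **Core** — 710 beads, one per globular histone residue, at the residue
  centres of mass. Charges follow the residue type (Lys/Arg +1e,
  Asp/Glu −1e, others 0), giving 116 positive, 64 negative and 530
  neutral beads (net +52e). Hard radius 0 (effective radius σ/2 = 2 Å).
* **Tails** — ten flexible chains (two copies each of the H2A N-tail,
  H2B, H3, H4 and the short H2A C-tail; 20/35/43/24/13 beads per copy,
  270 in total, net +94e), one bead per residue, charged beads with hard
  radius 0.6 Å.
* **DNA** — 74 units of five beads each (370 beads, −296e): a neutral
  central bead D (hard radius 4 Å, mass 4) representing two base pairs of
  bases+sugars, and four phosphate beads P (−1e, hard radius 1 Å) on two
  helical strands.
* **Ions** — explicit mobile counterions: K⁺ (hard radius 0), Mg²⁺
  (0.5 Å), CoHex³⁺ (cobalt(III)hexammine, 1.5 Å); Cl⁻ (radius 0) for
  added-salt systems. Counts enforce exact electroneutrality
  (150/75/50 per NCP for valence 1/2/3).

**Interactions.** The energy (kT units throughout; kT = 1) is a sum of

* Coulomb terms `U = l_B q_i q_j / r` in a dielectric continuum with
  ε = 78 at T = 298 K, giving a Bjerrum length l_B = 7.19 Å computed from
  CODATA constants at run time;
* a purely repulsive truncated-and-shifted (WCA) Lennard-Jones acting on
  the hard-core-shifted distance x = r − (R_i + R_j) with σ = 4 Å and
  ε_LJ = 1 kT, cut at x = 2^{1/6}σ. Directly bonded (1–2) pairs are
  excluded from the repulsion (several equilibrium bond lengths lie below
  contact) but kept in the Coulomb sum; both exclusions are switchable.
  Inside x where U would exceed 100 kT the potential continues linearly
  with constant inward force, so arbitrary overlaps (e.g. freshly placed
  ions) never produce non-finite forces;
* harmonic bonds `U = (k_b/2)(r − r_0)²` and angles
  `U = (k_a/2)(φ − φ_0)²`. The ½-prefactor convention is fixed by
  equipartition: a k_b = 5 kT/Å² bond then fluctuates with
  std √(kT/k_b) ≈ 0.45 Å, the reported ±0.5 Å scale.

**Bonded topology.**

* Core: every bead is bonded to its three nearest neighbours (the
  deduplicated union, so a bead can carry more than three bonds) with
  k_b = 5 kT/Å² and r_0 equal to the reference distance — an elastic
  network that keeps the octamer near-rigid while allowing fluctuations.
* Tails: chains with r_0 = 3.25 Å (peptide contour length per residue),
  k_b = 5 kT/Å², anchored to the nearest core bead at one end.
* DNA: the bond/angle set of the five-bead unit —
  D–P 9.62 Å (k 25 kT/Å²), D–D 6.8 Å (k 25), same-strand P–P 6.75 Å
  (k 25), minor-groove P–P 13.2 Å (k 5), D-D-D 180° (k 50 kT/rad²),
  strand angles 149° (k 100) and P-D-P 140° (k 100).
* DNA–core links: each D bead is tied to its nearest core bead with
  k_b = 5 kT/Å² at the construction distance. These links stand in for
  the ionic/hydrogen-bond contacts that hold DNA wrapped in the real
  particle.

**DNA construction geometry.** Phosphates sit on two helical strands at
radius ρ = 9.435 Å (fixed by the same-strand bond length at 36°/bp twist
and 3.4 Å/bp rise) with a strand-to-strand azimuthal phase of −149.37°,
chosen so the cross-strand same-base-pair distance is exactly the ideal
B-form value of 18.2 Å. The bond table and ideal B geometry are slightly
inconsistent (D–P is 9.587 Å at construction vs the 9.62 Å equilibrium;
the minor-groove pairs sit at 13.6 vs 13.2 Å), so construction is *near*,
not at, the bonded minimum; bonded-only relaxation moves the helix by
under ~0.3 Å RMSD, and in dynamics the cross-strand distance equilibrates
around 18.0 Å. The wrapped DNA places D beads on a left-handed 1.75-turn
superhelix (radius 45.0 Å so consecutive D chords stay 6.8 Å at the
canonical 23.9 Å pitch); phosphate frames are carried along the path with
rotation-minimizing (double-reflection) transport so the local helix
geometry is preserved to curvature order.

**Synthetic generator.** `make_synthetic_ncp(seed)` builds a fully
deterministic stand-in for a crystal-derived NCP: 710 core beads placed by
seeded rejection sampling (minimum spacing 4 Å) in a wedge-shaped
cylinder of radius 30 Å and height tapering 57→45 Å (octamer-like
dimensions; a larger radius would overlap the DNA superhelix), with the
exact 116/64/530 charge inventory and positive charges biased toward the
DNA path to emulate the surface charge mosaic. Tail sequences are
canonical histone termini except the H2A C-tail 13-mer, a synthetic
stand-in chosen so the ten tails carry exactly +94e. What the generator
does **not** emulate: the true fold (secondary-structure contact
topology) of the octamer, sequence-specific DNA geometry, and the real
tail exit points. Tests passing on synthetic models therefore validate
composition, topology, energetics and the analysis machinery — not
crystallographic realism; the `assemble_ncp(path)` route builds from a
deposited structure with the same inventory when one is available.

## Dynamics

Langevin dynamics, `m dv = F dt − γ v dt + ξ`, integrated with a BAOAB
splitting of velocity Verlet (the Ornstein-Uhlenbeck velocity step is
exact, so γ = 0 recovers symplectic velocity Verlet). Defaults follow the
study protocol: dt = 0.01, γ = 0.01 (weak friction — only equilibrium
averages are of interest and low γ samples configurations faster), kT = 1,
masses 1 except D beads (4), cubic periodic cell of edge 40 nm. Initial
velocities are Maxwell-Boltzmann at kT; all randomness flows from one
seeded generator and runs are bit-reproducible per seed. A short
steepest-descent minimization (capped step) precedes dynamics to relax
construction overlaps. A neighbour (Verlet) list with a 2 Å skin serves
the short-range repulsion; a bead moving more than half a skin triggers a
rebuild, and a per-period displacement above 10 Å aborts with a
diagnostic.

Electrostatics options: `direct` — minimum-image bare Coulomb over all
charged pairs, appropriate for the dilute systems simulated here (one NCP
of ~11 nm extent in a 40 nm cell) and the default for production runs;
`ewald`/`mesh` — a classic Ewald summation (real-space erfc + reciprocal
structure-factor sum, self-term) with parameters tuned to a requested
relative accuracy, validated against the NaCl Madelung constant to 1e-3
and used whenever fully periodic electrostatics matter. Periodic methods
require exact electroneutrality.

Equilibration: the leading 40% of frames are discarded before any
analysis (mirroring the 1e9-of-2.5e9-step discard of the full protocol).

## Observables

* **RDF** g(r) between group centres (the NCP centre is the centre of
  mass of the 710 core beads), shell-volume normalized against the mean
  partner density, bins in nm, minimum-image distances.
* **SDF** — number density of a species on a regular grid in a body
  frame built from three stored, well-separated core beads
  (orthonormal, right-handed; rigid motion of the NCP leaves body-frame
  coordinates unchanged). Grids export as text for iso-surface viewers.
* **P(r)/Rg/Dmax** — the equal-weight pair-distance histogram of all
  1350 beads (no scattering form factors: the comparison is of shapes and
  trends). Rg² = ½·((N−1)/N)·∫P r²dr, the correction restoring self
  pairs so two beads at distance d give exactly Rg = d/2. Dmax is the
  smallest r beyond which P stays under 1e-3 of its maximum (1 Å bins);
  the sub-threshold tail is zeroed and P renormalized.
* **RMSD** via Kabsch superposition (SVD with determinant sign fix).
* **DNA distance distributions** for the named pair classes
  (cross-strand same-bp, same-strand consecutive, D–D consecutive).
* **Stacking contacts**: NCP pairs with core-centre distance under 70 Å
  (≈ the first core-core RDF minimum; configurable). Reported per contact:
  the angle between dyad axes (each through the stored dyad reference
  sites: the core bead nearest the core centroid and the middle DNA D
  bead), folded to [0°, 90°], and a face classification — `stacked` when
  the cylinder axes (through the stored axis sites) are within 30° of
  parallel, `perpendicular` within 30° of orthogonal.
* **Bulk concentration**: ions within a 5 nm probe sphere centred at the
  grid point maximizing the minimum distance to all NCP centres,
  converted to mM.

## Problem sizes and numerical choices

Production-scale trajectories of the original protocol (1e8 steps for one
NCP, 2.5e9 for ten) are cluster-scale. The bundled tests and the
acceptance script run the same pipeline at desk scale, chosen as the
package's own validation sizes: 5e4–9e4 steps for the single-NCP runs
(frames every 200–300 steps, 40% discarded), 4e5–6e5 steps for the
bonded-pair thermostat check, and 1e4-step runs for the ion-condensation
comparison. Because the study friction γ = 0.01 makes single-bond energy
decorrelate only over ~1e4 steps, the bond-fluctuation observable is
measured on an ensemble of 50 non-interacting bonded pairs integrated
together — identical physics, ~50× the statistics per step. Ten-NCP
aggregation itself (dispersed with K⁺, partial clustering with Mg²⁺, one
compact aggregate with CoHex³⁺) needs NCP translational diffusion over
hundreds of Å and is not reachable at these sizes; the suite instead
verifies the exact Table-3 compositions of the ten-NCP systems and the
valence ordering of counterion condensation around a single NCP — the
screening/ion-correlation mechanism that drives the aggregation switch.

Other numerical choices: nearest-neighbour ties in the elastic network
and DNA-core linking resolve to the lower bead index (deterministic
builds); topology files store full float precision (`%.17g`) for lossless
round trips; energies/forces are validated against central finite
differences to 1e-4 relative; the Ewald accuracy target maps to
(α, r_cut, k_max) via standard erfc/Gaussian-tail estimates.

## Known limitations

* No attractive dispersion, hydrogen bonding or solvent-mediated
  oscillatory potentials: interactions are Coulomb + repulsion only, so
  e.g. tail contacts with the H2A acidic patch are underrepresented.
* The dielectric continuum with constant ε ignores solvent structure
  within ~8 Å ion-ion separations.
* DNA is sequence-independent and permanently wrapped (no breathing or
  unpeeling; the D-core links are permanent bonds).
* The reduced time unit has no calibrated physical mapping; only
  equilibrium properties are meaningful.
* The synthetic core reproduces inventory and dimensions, not the actual
  octamer fold; crystal-path builds depend on the deposited chain layout
  (H3/H4/H2A/H2B on chains A,E/B,F/C,G/D,H with 135/102/128/125 residues).
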