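"""Observables: RDFs, body-frame spatial distributions (SDF), SAXS-style
P(r)/Rg/Dmax, optimal-superposition RMSD, DNA distance distributions,
stacking-pair geometry and bulk ion concentration.

All analyses operate on production frames (equilibration discarded
upstream). Distances are computed with the minimum-image convention when a
periodic box is given. RDF bins are reported in nm, everything else in Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import NCPModel

AVOGADRO = 6.02214076e23


class AnalysisError(ValueError):
    pass


def _min_image_vec(d: np.ndarray, box: float | None) -> np.ndarray:
    if box:
        return d - box * np.round(d / box)
    return d


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------
@dataclass
class RDFResult:
    """g(r) between two bead groups; bins in nm."""

    r: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    label_a: str = "A"
    label_b: str = "B"


def rdf(
    frames_a,
    frames_b,
    box_edge: float,
    bin_width_nm: float = 0.1,
    r_max_nm: float | None = None,
    same_set: bool = False,
    label_a: str = "A",
    label_b: str = "B",
) -> RDFResult:
    """Centre-of-group radial distribution function.

    ``frames_a``/``frames_b``: sequences of (n_A, 3) and (n_B, 3) arrays in
    Å, one per production frame. Shell counts are normalized against the
    mean B density (ideal gas -> g = 1). With ``same_set=True`` the two
    sequences are the same particles and self pairs are skipped.
    """
    if bin_width_nm <= 0:
        raise AnalysisError("bin width must be > 0")
    if r_max_nm is None:
        r_max_nm = box_edge / 20.0  # Å/10 (nm) / 2
    nbins = int(math.ceil(r_max_nm / bin_width_nm))
    counts = np.zeros(nbins)
    n_frames = 0
    na = nb = 0
    for pa, pb in zip(frames_a, frames_b):
        pa = np.asarray(pa, dtype=float)
        pb = np.asarray(pb, dtype=float)
        na, nb = len(pa), len(pb)
        d = _min_image_vec(pa[:, None, :] - pb[None, :, :], box_edge)
        r = np.sqrt((d**2).sum(axis=2)) / 10.0  # nm
        if same_set:
            iu = np.triu_indices(na, k=1)
            r = r[iu]
        else:
            r = r.ravel()
        h, _ = np.histogram(r, bins=nbins, range=(0.0, nbins * bin_width_nm))
        counts += h
        n_frames += 1
    if n_frames == 0:
        raise AnalysisError("no frames")
    edges = np.arange(nbins + 1) * bin_width_nm
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    vol_nm3 = (box_edge / 10.0) ** 3
    if same_set:
        n_pairs = na * (nb - 1) / 2.0
    else:
        n_pairs = na * nb
    expected = n_frames * n_pairs * shell_vol / vol_nm3
    g = np.divide(counts, expected, out=np.zeros(nbins), where=expected > 0)
    centers = edges[:-1] + bin_width_nm / 2.0
    return RDFResult(r=centers, g=g, counts=counts, label_a=label_a,
                     label_b=label_b)


def group_centers(frames, indices) -> list[np.ndarray]:
    """Per-frame centre of mass of a bead group (equal masses), shape (1,3)."""
    return [f.positions[indices].mean(axis=0)[None, :] for f in frames]


# ---------------------------------------------------------------------------
# body-fixed frame + SDF
# ---------------------------------------------------------------------------
def local_frame(core_positions: np.ndarray, site_indices) -> tuple:
    """Orthonormal right-handed frame from three non-collinear sites.

    Returns (origin, R) with R rows = basis vectors; coordinates of a
    particle x in the frame are ``R @ (x - origin)``. Rigid motion of the
    body leaves frame coordinates unchanged.
    """
    i, j, k = site_indices
    p0 = np.asarray(core_positions[i], dtype=float)
    p1 = np.asarray(core_positions[j], dtype=float)
    p2 = np.asarray(core_positions[k], dtype=float)
    e1 = p1 - p0
    n1 = np.linalg.norm(e1)
    cr = np.cross(e1, p2 - p0)
    n3 = np.linalg.norm(cr)
    if n1 < 1e-10 or n3 < 1e-8 * max(n1, 1.0):
        raise AnalysisError("frame sites are collinear")
    e1 /= n1
    e3 = cr / n3
    e2 = np.cross(e3, e1)
    origin = (p0 + p1 + p2) / 3.0
    return origin, np.stack([e1, e2, e3])


@dataclass
class SDFGrid:
    """Number density on a regular grid in the NCP local frame (Å)."""

    density: np.ndarray
    voxel_edge: float
    origin_corner: np.ndarray
    frame_sites: tuple

    def integral(self) -> float:
        return float(self.density.sum() * self.voxel_edge**3)

    def write_text(self, path) -> None:
        """Documented text dump: header + one voxel density per line."""
        nx, ny, nz = self.density.shape
        with open(path, "w") as fh:
            fh.write("# nucleocg sdf grid v1\n")
            fh.write(f"# shape {nx} {ny} {nz} voxel {self.voxel_edge:.6g}\n")
            oc = self.origin_corner
            fh.write(f"# corner {oc[0]:.6g} {oc[1]:.6g} {oc[2]:.6g}\n")
            for v in self.density.ravel():
                fh.write(f"{v:.8g}\n")


def sdf(
    frames,
    frame_sites,
    species_indices,
    voxel_edge: float = 4.0,
    half_extent: float = 80.0,
    box_edge: float | None = None,
    reference_indices=None,
) -> SDFGrid:
    """Spatial distribution of a species in the NCP body frame.

    For each frame the local frame is built from ``frame_sites`` (indices
    into the full bead array, normally three well-separated core beads) and
    species positions are binned in that frame, averaged over frames. The
    grid covers [-half_extent, half_extent]^3; density integrates to the
    mean in-grid particle count per frame.
    """
    if voxel_edge <= 0:
        raise AnalysisError("voxel edge must be > 0")
    nbin = int(round(2 * half_extent / voxel_edge))
    hist = np.zeros((nbin, nbin, nbin))
    n_frames = 0
    edges = np.linspace(-half_extent, half_extent, nbin + 1)
    ref = reference_indices if reference_indices is not None else frame_sites
    for f in frames:
        pos = f.positions
        origin, R = local_frame(pos, frame_sites)
        rel = _min_image_vec(pos[species_indices] - origin, box_edge)
        xyz = rel @ R.T
        h, _ = np.histogramdd(xyz, bins=(edges, edges, edges))
        hist += h
        n_frames += 1
    if n_frames == 0:
        raise AnalysisError("no frames")
    density = hist / (n_frames * voxel_edge**3)
    return SDFGrid(
        density=density,
        voxel_edge=voxel_edge,
        origin_corner=np.array([-half_extent] * 3),
        frame_sites=tuple(frame_sites),
    )


# ---------------------------------------------------------------------------
# P(r), Rg, Dmax
# ---------------------------------------------------------------------------
@dataclass
class PrCurve:
    """Normalized intra-particle distance distribution with Rg and Dmax (Å)."""

    r: np.ndarray
    p: np.ndarray
    rg: float
    dmax: float
    bin_width: float


def pr_rg_dmax(
    frames,
    selection,
    bin_width: float = 1.0,
    dmax_threshold: float = 1e-3,
) -> PrCurve:
    """Ensemble-averaged P(r) over all bead pairs of the selection.

    All beads enter with equal weight (no scattering form factors). The
    radius of gyration comes from the second moment,
    Rg² = (1/2)·((N−1)/N)·∫P(r) r² dr — the (N−1)/N factor restores the
    self-pair term so that two beads at distance d give Rg = d/2 exactly.
    Dmax is the smallest r beyond which P stays below ``dmax_threshold``
    of its maximum; the (sub-threshold) tail past Dmax is zeroed and P
    renormalized to unit area.
    """
    selection = np.asarray(selection, dtype=int)
    n_sel = len(selection)
    if n_sel < 2:
        raise AnalysisError("P(r) needs at least two selected beads")
    if bin_width <= 0:
        raise AnalysisError("bin width must be > 0")
    frames = list(frames)
    if not frames:
        raise AnalysisError("no frames")
    # first frame fixes the histogram range generously
    pos0 = _frame_positions(frames[0], selection)
    span = np.linalg.norm(pos0.max(axis=0) - pos0.min(axis=0)) * 2.0 + 10.0
    nbins = int(math.ceil(span / bin_width))
    hist = np.zeros(nbins, dtype=np.int64)
    for f in frames:
        pos = np.ascontiguousarray(_frame_positions(f, selection))
        hist += _kernels.pair_distance_hist(pos, bin_width, nbins)
    total = hist.sum()
    p = hist / (total * bin_width)
    pmax = p.max()
    above = np.flatnonzero(p > dmax_threshold * pmax)
    last = int(above[-1])
    dmax = (last + 1) * bin_width
    p = p.copy()
    p[last + 1:] = 0.0
    p /= p.sum() * bin_width
    centers = (np.arange(nbins) + 0.5) * bin_width
    rg2 = 0.5 * (n_sel - 1) / n_sel * float((p * centers**2).sum() * bin_width)
    keep = last + 1
    return PrCurve(
        r=centers[:keep], p=p[:keep], rg=float(np.sqrt(rg2)), dmax=float(dmax),
        bin_width=bin_width,
    )


def _frame_positions(frame, selection):
    pos = frame.positions if hasattr(frame, "positions") else np.asarray(frame)
    if callable(pos):
        pos = pos()
    return np.asarray(pos, dtype=float)[selection]


# ---------------------------------------------------------------------------
# RMSD (optimal rigid superposition)
# ---------------------------------------------------------------------------
def rmsd(reference: np.ndarray, coords: np.ndarray, selection=None) -> float:
    """Minimum RMSD over rigid motions (Kabsch superposition), in Å."""
    ref = np.asarray(reference, dtype=float)
    x = np.asarray(coords, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        ref = ref[sel]
        x = x[sel]
    if ref.shape != x.shape:
        raise AnalysisError("selection sizes differ")
    if len(ref) < 3:
        raise AnalysisError("RMSD needs at least 3 points")
    ref0 = ref - ref.mean(axis=0)
    x0 = x - x.mean(axis=0)
    h = x0.T @ ref0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s[-1] *= d
    msd = max(
        0.0,
        ((ref0**2).sum() + (x0**2).sum() - 2.0 * s.sum()) / len(ref),
    )
    return float(np.sqrt(msd))


def rmsd_series(frames, reference, selection) -> np.ndarray:
    return np.array(
        [rmsd(reference, f.positions, selection) for f in frames]
    )


# ---------------------------------------------------------------------------
# DNA distance distributions
# ---------------------------------------------------------------------------
def distance_distributions(frames, pair_sets: dict) -> dict:
    """Mean ± std of named index-pair distances over production frames.

    ``pair_sets`` maps names to (i_indices, j_indices); see
    :func:`nucleocg.ncp_builder.dna_pair_indices`.
    """
    out = {}
    frames = list(frames)
    for name, (i_idx, j_idx) in pair_sets.items():
        samples = []
        for f in frames:
            d = np.linalg.norm(f.positions[i_idx] - f.positions[j_idx], axis=1)
            samples.append(d)
        arr = np.concatenate(samples)
        out[name] = (float(arr.mean()), float(arr.std()))
    return out


# ---------------------------------------------------------------------------
# stacking geometry
# ---------------------------------------------------------------------------
@dataclass
class StackingContact:
    frame_index: int
    ncp_a: int
    ncp_b: int
    center_distance: float      # Å
    dyad_angle_deg: float       # folded to [0, 90]
    axis_angle_deg: float
    classification: str         # stacked | perpendicular | other


def stacking_pairs(
    frames,
    model: NCPModel,
    cutoff: float = 70.0,
    box_edge: float | None = None,
    parallel_tol_deg: float = 30.0,
) -> list[StackingContact]:
    """Contacting NCP pairs with dyad-axis angles and face classification.

    A pair is a contact when the core-centre distance is below ``cutoff``
    (default 70 Å ≈ the first core-core RDF minimum). The dyad axis of
    each NCP runs through its two stored dyad reference sites; the
    cylinder axis through the stored axis sites. ``stacked`` means the
    cylinder axes are within ``parallel_tol_deg`` of parallel,
    ``perpendicular`` within the same tolerance of orthogonal.
    """
    if model.n_ncp < 2:
        raise AnalysisError("stacking analysis needs at least two NCPs")
    specs = []
    for i in range(model.n_ncp):
        try:
            specs.append(
                (
                    model.group(f"ncp{i}/core"),
                    model.group(f"ncp{i}/dyad_sites"),
                    model.group(f"ncp{i}/axis_sites"),
                )
            )
        except KeyError as exc:
            raise AnalysisError(f"missing dyad/axis sites for NCP {i}") from exc
    contacts = []
    for fi, f in enumerate(frames):
        pos = f.positions
        centers = [pos[c].mean(axis=0) for c, _, _ in specs]
        dyads = []
        axes = []
        for core_idx, dyad_idx, axis_idx in specs:
            d = pos[dyad_idx[1]] - pos[dyad_idx[0]]
            dyads.append(d / np.linalg.norm(d))
            a = pos[axis_idx[1]] - pos[axis_idx[0]]
            axes.append(a / np.linalg.norm(a))
        for i in range(model.n_ncp):
            for j in range(i + 1, model.n_ncp):
                dv = _min_image_vec(centers[i] - centers[j], box_edge)
                dist = float(np.linalg.norm(dv))
                if dist >= cutoff:
                    continue
                dyad_angle = math.degrees(
                    math.acos(min(1.0, abs(float(dyads[i] @ dyads[j]))))
                )
                axis_angle = math.degrees(
                    math.acos(min(1.0, abs(float(axes[i] @ axes[j]))))
                )
                if axis_angle <= parallel_tol_deg:
                    cls = "stacked"
                elif axis_angle >= 90.0 - parallel_tol_deg:
                    cls = "perpendicular"
                else:
                    cls = "other"
                contacts.append(
                    StackingContact(fi, i, j, dist, dyad_angle, axis_angle, cls)
                )
    return contacts


# ---------------------------------------------------------------------------
# bulk ion concentration
# ---------------------------------------------------------------------------
def bulk_concentration(
    frames,
    ion_indices,
    ncp_center_groups,
    box_edge: float,
    probe_radius: float = 50.0,
    grid_points: int = 12,
) -> float:
    """Ion concentration (mM) at the point farthest from every NCP centre.

    Per frame, a regular grid locates the position maximizing the minimum
    minimum-image distance to all NCP core centres; ions within
    ``probe_radius`` of it are counted and converted to molarity.
    """
    ion_indices = np.asarray(ion_indices, dtype=int)
    grid_1d = (np.arange(grid_points) + 0.5) * box_edge / grid_points
    gx, gy, gz = np.meshgrid(grid_1d, grid_1d, grid_1d, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    counts = []
    n_any = 0
    for f in frames:
        pos = f.positions
        centers = np.array([pos[g].mean(axis=0) for g in ncp_center_groups])
        d = _min_image_vec(grid[:, None, :] - centers[None, :, :], box_edge)
        dmin = np.sqrt((d**2).sum(axis=2)).min(axis=1)
        probe = grid[int(np.argmax(dmin))]
        dv = _min_image_vec(pos[ion_indices] - probe, box_edge)
        n_in = int((np.sqrt((dv**2).sum(axis=1)) < probe_radius).sum())
        counts.append(n_in)
        n_any += 1
    if n_any == 0:
        raise AnalysisError("no frames")
    vol_l = 4.0 / 3.0 * np.pi * probe_radius**3 * 1e-27  # Å³ → L
    molar = np.mean(counts) / (AVOGADRO * vol_l)
    return float(molar * 1e3)
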