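"""Profiles along the bilayer normal and radial distribution functions.

The reaction coordinate ξ of a site is its signed periodic z-offset from a
bilayer midplane (the mean of the two leaflet-grid mean heights), with
negative ξ on the external-solution side — so a cation approaching from
the outside runs from ξ ≈ −4.5 nm up through 0 at the bilayer center.
The bilayer normal is fixed to the z axis (planar geometry).

Default bin widths: 0.05 nm for densities, 0.1 nm for orientation
profiles, 0.01 nm for RDFs — fine enough to resolve the 0.7 nm first
coordination shell that defines tail–tail contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_io import Frame, RoleMap, select, wrap_z
from .surface import BilayerSurfaces

logger = logging.getLogger("cgmem")


@dataclass
class DensityProfile:
    """Number density (nm⁻³) of a site group binned by ξ."""

    bin_centers: np.ndarray
    values: np.ndarray
    group_label: str
    n_frames: int
    bin_width: float

    def integral(self, box_area: float) -> float:
        """Σ values · bin volume — the mean site count of the group."""
        return float(self.values.sum() * box_area * self.bin_width)


@dataclass
class OrientationProfile:
    """Mean cos θ of the cation tail→head vector vs the outward bilayer
    normal, binned by head-site ξ.  Empty bins hold NaN (flagged by
    ``counts == 0``, never interpolated)."""

    bin_centers: np.ndarray
    mean_cos_theta: np.ndarray
    counts: np.ndarray
    smooth_window: int


@dataclass
class RDF:
    """Radial distribution function g(r) between two site groups.

    ``counts`` are raw ordered-pair counts per bin (self-pairs excluded),
    kept so exact oracles can compare bin-for-bin."""

    r: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    bin_width: float
    n_frames: int


# ---------------------------------------------------------------------------
# Site selectors
# ---------------------------------------------------------------------------

def molecule_centroids(frame: Frame, role_map: RoleMap, role: str) -> np.ndarray:
    """Per-molecule center of geometry of the beads carrying `role`
    (e.g. the imidazolium-ring centroid from cation_head beads).

    The centroid is computed under the minimum image about each molecule's
    first such bead, then wrapped back into the box, so molecules straddling
    the boundary are handled correctly."""
    groups = select(frame, role_map, role)
    if not groups:
        return np.empty((0, 3))
    L = frame.box.lengths
    out = np.empty((len(groups), 3))
    for row, (mol, idx) in enumerate(sorted(groups.items())):
        p = frame.positions[idx]
        ref = p[0]
        d = p - ref
        d -= L * np.round(d / L)
        out[row] = np.mod(ref + d.mean(axis=0), L)
    return out


# ---------------------------------------------------------------------------
# ξ coordinate
# ---------------------------------------------------------------------------

def xi_coordinate(
    positions: np.ndarray,
    surfaces: BilayerSurfaces,
    bilayer: int = 1,
) -> np.ndarray:
    """Signed distance ξ (nm) of positions from a bilayer midplane.

    Negative ξ lies on the external-solution side: below the midplane for
    bilayer 1, above it for bilayer 2 (label order b1_external …
    b2_external runs upward in z).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    mid = surfaces.midplane(bilayer)
    dz = wrap_z(positions[:, 2] - mid, surfaces.box.Lz)
    return np.asarray(dz if bilayer == 1 else -dz, dtype=float)


def pick_reported_bilayer(
    frames,
    surfaces_per_frame,
    site_fn,
) -> int:
    """Which bilayer to report on: the one with more of the group's sites
    incorporated (|ξ| within the bilayer slab) over the analysis window."""
    scores = [0, 0]
    for frame, surfaces in zip(frames, surfaces_per_frame):
        sites = site_fn(frame)
        if sites.size == 0:
            continue
        labels = surfaces.locate(sites)
        scores[0] += int(np.sum(labels == "bilayer1"))
        scores[1] += int(np.sum(labels == "bilayer2"))
    return 1 if scores[0] >= scores[1] else 2


# ---------------------------------------------------------------------------
# Density profile
# ---------------------------------------------------------------------------

def density_profile(
    frames,
    surfaces_per_frame,
    site_fn,
    bin_width: float = 0.05,
    bilayer: int = 1,
    xi_range: tuple[float, float] | None = None,
    group_label: str = "",
) -> DensityProfile:
    """Number-density profile of a site group along ξ.

    `site_fn(frame) -> (M, 3) positions` extracts the group's reference
    sites per frame (see :func:`molecule_centroids`).  Each frame's ξ
    values are histogrammed and normalized by the slab volume
    Lx·Ly·bin_width and the frame count, so the profile integrates to the
    mean site count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    box = frames[0].box
    if xi_range is None:
        half = box.Lz / 2
        xi_range = (-half, half)
    edges = np.arange(xi_range[0], xi_range[1] + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    empty = True
    for frame, surfaces in zip(frames, surfaces_per_frame):
        sites = site_fn(frame)
        if sites.size == 0:
            continue
        empty = False
        xi = xi_coordinate(sites, surfaces, bilayer)
        c, _ = np.histogram(xi, bins=edges)
        counts += c
    if empty:
        logger.warning("density_profile: group %r empty in every frame", group_label)
    values = counts / (len(frames) * box.Lx * box.Ly * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, values, group_label, len(frames), bin_width)


# ---------------------------------------------------------------------------
# Orientation profile
# ---------------------------------------------------------------------------

def running_mean(y: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean ignoring NaNs; window 1 is the identity."""
    if window <= 1:
        return np.asarray(y, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    half_lo = (window - 1) // 2
    half_hi = window - half_lo
    for i in range(y.size):
        seg = y[max(0, i - half_lo): i + half_hi]
        good = np.isfinite(seg)
        out[i] = seg[good].mean() if good.any() else np.nan
    return out


def orientation_profile(
    frames,
    surfaces_per_frame,
    role_map: RoleMap,
    bin_width: float = 0.1,
    bilayer: int = 1,
    xi_range: tuple[float, float] | None = None,
    smooth_window: int = 4,
) -> OrientationProfile:
    """Mean cation orientation cos θ along ξ.

    For each cation, v points from its hydrophobic-site (cation_tail)
    centroid to its hydrophilic-site (cation_head) centroid; cos θ is the
    projection of v̂ on the outward normal, the +z axis flipped so that
    positive cos θ means the head points away from the bilayer center.
    Values are binned by the head-site ξ and a centered running mean of
    `smooth_window` bins is applied last.  Cations with zero-length v are
    skipped (counted in the log).
    """
    frames = list(frames)
    box = frames[0].box
    if xi_range is None:
        half = box.Lz / 2
        xi_range = (-half, half)
    edges = np.arange(xi_range[0], xi_range[1] + bin_width / 2, bin_width)
    sums = np.zeros(edges.size - 1)
    counts = np.zeros(edges.size - 1, dtype=int)
    n_skipped = 0
    L = box.lengths
    for frame, surfaces in zip(frames, surfaces_per_frame):
        heads = molecule_centroids(frame, role_map, "cation_head")
        tails = molecule_centroids(frame, role_map, "cation_tail")
        if heads.shape != tails.shape or heads.size == 0:
            continue
        v = heads - tails
        v -= L * np.round(v / L)
        norms = np.linalg.norm(v, axis=1)
        ok = norms > 1e-12
        n_skipped += int((~ok).sum())
        xi_head = xi_coordinate(heads, surfaces, bilayer)
        mid = surfaces.midplane(bilayer)
        dz = wrap_z(heads[:, 2] - mid, box.Lz)
        outward = np.where(dz >= 0, 1.0, -1.0)
        cos = np.where(ok, v[:, 2] * outward / np.where(ok, norms, 1.0), np.nan)
        which = np.digitize(xi_head[ok], edges) - 1
        valid = (which >= 0) & (which < counts.size)
        np.add.at(sums, which[valid], cos[ok][valid])
        np.add.at(counts, which[valid], 1)
    if n_skipped:
        logger.info("orientation_profile: skipped %d zero-length vectors", n_skipped)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    smoothed = running_mean(mean, smooth_window)
    smoothed[counts == 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return OrientationProfile(centers, smoothed, counts, smooth_window)


# ---------------------------------------------------------------------------
# Radial distribution function
# ---------------------------------------------------------------------------

def rdf(
    frames,
    site_fn_a,
    site_fn_b=None,
    r_max: float = 2.0,
    dr: float = 0.01,
) -> RDF:
    """g(r) between two site groups under the minimum image.

    Pair counting uses a periodic KD-tree; bin i holds ordered pairs with
    distance in (r_i, r_{i+1}] so exactly coincident (self) pairs never
    contribute.  When the two groups are the same function, self-pairs are
    excluded and the ideal-gas normalization uses N−1 partners.
    Requires r_max ≤ min(box)/2.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    frames = list(frames)
    box = frames[0].box
    if r_max > min(box.lengths) / 2 + 1e-12:
        raise ValueError(f"r_max {r_max} exceeds half the box minimum edge")
    same = site_fn_b is None
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(edges.size - 1)
    norm = np.zeros(edges.size - 1)
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    for frame in frames:
        A = np.mod(site_fn_a(frame), box.lengths)
        B = A if same else np.mod(site_fn_b(frame), box.lengths)
        if len(A) == 0 or len(B) == 0:
            continue
        ta = cKDTree(A, boxsize=box.lengths)
        tb = ta if same else cKDTree(B, boxsize=box.lengths)
        cum = ta.count_neighbors(tb, edges)  # ordered pairs with d <= r
        counts += np.diff(cum)  # (r_i, r_{i+1}]; drops d = 0 self-pairs
        n_partners = len(B) - 1 if same else len(B)
        norm += len(A) * n_partners / box.volume * shell
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(norm > 0, counts / norm, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDF(centers, g, counts, dr, len(frames))


def first_minimum(
    rdf_curve: RDF, smooth_bins: int = 3, min_prominence: float = 0.05
) -> float:
    """First local minimum of g(r) after its first maximum — the contact
    (first-shell) cutoff suggestion.

    A `smooth_bins` moving average is applied first, and both extrema must
    have a prominence of at least `min_prominence` × the g(r) range so that
    bin-level noise is not mistaken for shell structure.  Raises if g(r)
    has no such maximum-then-minimum structure (e.g. monotone)."""
    from scipy.signal import find_peaks

    g = running_mean(rdf_curve.g, smooth_bins)
    r = rdf_curve.r
    if g.size < 5:
        raise ValueError("need at least 5 RDF bins")
    prom = min_prominence * float(np.ptp(g))
    peaks, _ = find_peaks(g, prominence=prom)
    if peaks.size == 0:
        raise ValueError("g(r) has no prominent first maximum")
    minima, _ = find_peaks(-g, prominence=prom)
    minima = minima[minima > peaks[0]]
    if minima.size == 0:
        raise ValueError("g(r) has no local minimum after its first maximum")
    return float(r[minima[0]])
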