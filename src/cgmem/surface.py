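"""Leaflet surface grids and bilayer morphology.

The phosphate beads of each leaflet are interpolated into a periodic height
field z(x, y) (piecewise-linear over a Delaunay triangulation, with
periodic ghost images so the field has no holes and matches across the box
boundary).  The four leaflet grids of a two-bilayer system then yield the
morphology observables: true (undulation-corrected) surface area, bilayer
thickness, the volumes of the two bilayers and of the internal and external
aqueous compartments, per-lipid areas and volumes, and point-in-compartment
queries used for concentration tracking.

Conventions (documented, configurable):
  * surfaces are single-valued height fields z(x, y); overhangs or pores
    are outside the contract and raise errors;
  * thickness is the node-wise vertical (z) separation of the two leaflet
    grids under the periodic minimum image, not a surface-normal distance;
  * the z axis is periodic: the external compartment is the one wrapping
    through the z boundary once labels are assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .core_io import Frame, RoleMap, SimulationBox, wrap_z

logger = logging.getLogger("cgmem")

LEAFLET_LABELS = ("b1_external", "b1_internal", "b2_internal", "b2_external")
COMPARTMENTS = ("external", "bilayer1", "internal", "bilayer2")


class LeafletAssignmentError(ValueError):
    """Phosphate z values do not separate into four leaflet groups."""


class SurfaceGeometryError(ValueError):
    """Leaflet surfaces cross or are otherwise inconsistent."""


@dataclass
class LeafletGrid:
    """Periodic height field of one leaflet on an nx × ny node grid.

    Node (i, j) sits at (i·Lx/nx, j·Ly/ny); heights are continuous in z
    (unwrapped about the leaflet's circular mean, so a leaflet straddling
    the periodic z boundary is stored without a jump)."""

    heights: np.ndarray
    box: SimulationBox
    label: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("non-finite grid height")

    @property
    def nx(self) -> int:
        return self.heights.shape[0]

    @property
    def ny(self) -> int:
        return self.heights.shape[1]

    @property
    def mean_height(self) -> float:
        return float(self.heights.mean())

    def interpolate(self, x, y) -> np.ndarray:
        """Bilinear periodic interpolation of the height field at (x, y)."""
        x = np.mod(np.asarray(x, dtype=float), self.box.Lx)
        y = np.mod(np.asarray(y, dtype=float), self.box.Ly)
        dx, dy = self.box.Lx / self.nx, self.box.Ly / self.ny
        fi, fj = x / dx, y / dy
        i0 = np.floor(fi).astype(int) % self.nx
        j0 = np.floor(fj).astype(int) % self.ny
        i1, j1 = (i0 + 1) % self.nx, (j0 + 1) % self.ny
        ti, tj = fi - np.floor(fi), fj - np.floor(fj)
        h = self.heights
        return (
            h[i0, j0] * (1 - ti) * (1 - tj)
            + h[i1, j0] * ti * (1 - tj)
            + h[i0, j1] * (1 - ti) * tj
            + h[i1, j1] * ti * tj
        )


def default_resolution(n_points: int) -> int:
    """Default grid resolution: ⌈√(2·n)⌉ capped at 128 (≈ two nodes per
    phosphate)."""
    return min(128, int(np.ceil(np.sqrt(2 * n_points))))


# ---------------------------------------------------------------------------
# Leaflet assignment
# ---------------------------------------------------------------------------

def assign_leaflets(
    frame: Frame,
    role_map: RoleMap,
    external: str = "auto",
    gap_ratio: float = 2.0,
) -> dict:
    """Partition phosphate beads into the four leaflets of a two-bilayer
    system.

    The sorted phosphate z values (circular along the periodic z axis) are
    split at their 4 largest circular gaps.  Separability requires the 4th
    largest gap to exceed `gap_ratio` × the 5th largest; otherwise a
    :class:`LeafletAssignmentError` with gap diagnostics is raised (e.g.
    for a single-bilayer frame).

    `external` picks which of the two aqueous gaps is the external
    solution: "auto" (the gap holding more cation_head/anion beads, falling
    back to the wider gap), "widest", or "wrap" (the gap containing z = 0).
    Returns ``{label: bead index array}`` for the four labels
    b1_external, b1_internal, b2_internal, b2_external, ordered upward in z
    starting just above the external gap.
    """
    mask = role_map.mask(frame, "phosphate")
    idx = np.nonzero(mask)[0]
    if idx.size < 12:
        raise LeafletAssignmentError(
            f"only {idx.size} phosphates; need >= 3 per leaflet"
        )
    Lz = frame.box.Lz
    z = np.mod(frame.positions[idx, 2], Lz)
    order = np.argsort(z)
    zs = z[order]
    gaps = np.diff(zs, append=zs[0] + Lz)  # gap after each sorted point
    gorder = np.argsort(gaps)[::-1]
    if zs.size > 4 and gaps[gorder[3]] < gap_ratio * gaps[gorder[4]]:
        raise LeafletAssignmentError(
            "leaflets not separable: largest circular gaps "
            f"{np.sort(gaps)[::-1][:6].round(3).tolist()} nm lack a 4-group "
            f"break (4th/5th ratio < {gap_ratio})"
        )
    cut_after = np.sort(gorder[:4])  # sorted positions after which a gap opens

    groups = []  # (start_z, bead indices) in circular order
    for a, b in zip(cut_after, np.roll(cut_after, -1)):
        sel = (
            order[a + 1: b + 1]
            if b > a
            else np.concatenate([order[a + 1:], order[: b + 1]])
        )
        groups.append((zs[(a + 1) % zs.size], idx[sel]))

    # the two aqueous gaps are the two widest of the four chosen cuts;
    # identify the groups bounding them
    gap_sizes = gaps[cut_after]
    aq = np.argsort(gap_sizes)[::-1][:2]  # positions (in cut order) of the
    # two aqueous gaps; the external one starts the label sequence
    if external == "widest":
        ext_cut = aq[0]
    elif external == "wrap":
        # the wrap gap is the one whose interval extends past z = Lz
        ends = zs[cut_after] + gaps[cut_after]
        ext_cut = int(np.argmax(ends >= Lz))
    elif external == "auto":
        ion_mask = role_map.mask(frame, "cation_head") | role_map.mask(frame, "anion")
        ion_z = np.mod(frame.positions[ion_mask, 2], Lz)
        counts = []
        for c in aq:
            lo = zs[cut_after[c]]
            width = gaps[cut_after[c]]
            counts.append(int(np.sum(np.mod(ion_z - lo, Lz) < width)))
        if counts[0] == counts[1]:
            ext_cut = int(aq[np.argmax(gap_sizes[aq])])
        else:
            ext_cut = int(aq[int(np.argmax(counts))])
    else:
        raise ValueError(f"unknown external convention {external!r}")

    # labels proceed upward in z from the group just above the external gap
    # (groups[i] is the group immediately above gap i)
    result = {}
    for k, label in enumerate(LEAFLET_LABELS):
        _, beads = groups[(ext_cut + k) % 4]
        result[label] = beads
        logger.debug("leaflet %s: %d phosphates", label, beads.size)
    return result


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

def build_leaflet_grid(
    points: np.ndarray,
    box: SimulationBox,
    nx: int | None = None,
    ny: int | None = None,
    label: str = "",
    margin: float | None = None,
) -> LeafletGrid:
    """Interpolate scattered phosphate positions into a periodic height
    field.

    (x, y) points are augmented with periodic ghost images within `margin`
    (default 2·√(Lx·Ly/n), generous enough that the Delaunay hull covers
    the whole box for quasi-uniform points) and piecewise-linearly
    interpolated onto the node grid.  z values are unwrapped about their
    circular mean first, so leaflets straddling the z boundary stay
    continuous.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 3:
        raise ValueError("need an (n >= 3, 3) point array")
    n = points.shape[0]
    if nx is None:
        nx = default_resolution(n)
    if ny is None:
        ny = nx
    if margin is None:
        margin = 2.0 * np.sqrt(box.Lx * box.Ly / n)

    xy = np.mod(points[:, :2], [box.Lx, box.Ly])
    # unwrap z about a circular reference so the field is continuous
    z_ref = points[0, 2]
    z = z_ref + wrap_z(points[:, 2] - z_ref, box.Lz)
    z = np.asarray(z) - box.Lz * np.floor(np.mean(z) / box.Lz)  # mean into [0, Lz)

    ghosts_xy, ghosts_z = [xy], [z]
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            shifted = xy + np.array([sx * box.Lx, sy * box.Ly])
            keep = (
                (shifted[:, 0] >= -margin)
                & (shifted[:, 0] <= box.Lx + margin)
                & (shifted[:, 1] >= -margin)
                & (shifted[:, 1] <= box.Ly + margin)
            )
            if keep.any():
                ghosts_xy.append(shifted[keep])
                ghosts_z.append(z[keep])
    all_xy = np.vstack(ghosts_xy)
    all_z = np.concatenate(ghosts_z)

    try:
        interp = LinearNDInterpolator(all_xy, all_z)
    except QhullError as exc:
        raise ValueError(f"cannot triangulate leaflet points: {exc}") from exc

    gx = np.arange(nx) * box.Lx / nx
    gy = np.arange(ny) * box.Ly / ny
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    H = interp(GX, GY)
    if np.isnan(H).any():
        raise ValueError(
            f"{int(np.isnan(H).sum())} uncovered grid nodes; increase the "
            f"ghost margin (currently {margin:.3g} nm)"
        )
    return LeafletGrid(H, box, label)


# ---------------------------------------------------------------------------
# Morphology metrics
# ---------------------------------------------------------------------------

def surface_area(grid: LeafletGrid) -> float:
    """True area of the periodic height field: sum over the 2·nx·ny
    triangles tiling it.  Equals Lx·Ly exactly for a flat field and is
    never smaller."""
    h = grid.heights
    dx, dy = grid.box.Lx / grid.nx, grid.box.Ly / grid.ny
    h10 = np.roll(h, -1, axis=0)
    h01 = np.roll(h, -1, axis=1)
    h11 = np.roll(h10, -1, axis=1)
    # cell corners: (0,0)=h, (dx,0)=h10, (0,dy)=h01, (dx,dy)=h11
    # triangle 1: (0,0)-(dx,0)-(dx,dy); triangle 2: (0,0)-(dx,dy)-(0,dy)
    a1 = np.sqrt((dy * (h10 - h)) ** 2 + (dx * (h10 - h11)) ** 2 + (dx * dy) ** 2)
    a2 = np.sqrt((dy * (h01 - h)) ** 2 + (dx * (h01 - h11)) ** 2 + (dx * dy) ** 2)
    return float(0.5 * (a1.sum() + a2.sum()))


def bilayer_thickness(grid_upper: LeafletGrid, grid_lower: LeafletGrid) -> float:
    """Mean node-wise periodic-minimum vertical separation of two leaflet
    grids (nm)."""
    if grid_upper.heights.shape != grid_lower.heights.shape:
        raise ValueError("grids must share resolution")
    if grid_upper.box != grid_lower.box:
        raise ValueError("grids must share the box")
    dz = wrap_z(grid_upper.heights - grid_lower.heights, grid_upper.box.Lz)
    return float(np.abs(dz).mean())


@dataclass
class BilayerSurfaces:
    """The four leaflet grids of a two-bilayer system, in label order
    (b1_external, b1_internal, b2_internal, b2_external upward in z)."""

    grids: tuple
    box: SimulationBox

    def __post_init__(self) -> None:
        if len(self.grids) != 4:
            raise ValueError("need exactly four leaflet grids")
        shapes = {g.heights.shape for g in self.grids}
        if len(shapes) != 1:
            raise ValueError("leaflet grids must share resolution")

    @classmethod
    def from_frame(
        cls,
        frame: Frame,
        role_map: RoleMap,
        nx: int | None = None,
        ny: int | None = None,
        external: str = "auto",
    ) -> "BilayerSurfaces":
        """Assign leaflets and build all four grids from one frame."""
        leaflets = assign_leaflets(frame, role_map, external=external)
        if nx is None:
            nx = default_resolution(
                min(v.size for v in leaflets.values())
            )
        grids = tuple(
            build_leaflet_grid(
                frame.positions[leaflets[label]], frame.box, nx, ny or nx, label
            )
            for label in LEAFLET_LABELS
        )
        return cls(grids, frame.box)

    def _column_intervals(self):
        """Per-node cyclic interval lengths (bilayer1, internal, bilayer2,
        external), each ≥ 0, summing to Lz."""
        Lz = self.box.Lz
        H = [g.heights for g in self.grids]
        d = [np.mod(H[(k + 1) % 4] - H[k], Lz) for k in range(4)]
        total = d[0] + d[1] + d[2] + d[3]
        bad = ~np.isclose(total, Lz, rtol=0, atol=1e-9 * Lz)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SurfaceGeometryError(
                f"leaflet surfaces cross at grid column ({i}, {j})"
            )
        # d[0]: b1_ext→b1_int = bilayer1; d[1]: internal; d[2]: bilayer2;
        # d[3]: external (wraps through the z boundary)
        return {"bilayer1": d[0], "internal": d[1], "bilayer2": d[2], "external": d[3]}

    def compartment_volumes(self) -> dict:
        """Volumes (nm³) of the four compartments; they sum to the box
        volume exactly up to float accumulation."""
        cell = self.box.Lx * self.box.Ly / self.grids[0].heights.size
        return {k: float(v.sum() * cell) for k, v in self._column_intervals().items()}

    def midplane(self, bilayer: int) -> float:
        """Mean-height midplane of bilayer 1 or 2 (nm, periodic-safe)."""
        if bilayer == 1:
            lo, hi = self.grids[0], self.grids[1]
        elif bilayer == 2:
            lo, hi = self.grids[2], self.grids[3]
        else:
            raise ValueError("bilayer must be 1 or 2")
        m_lo = lo.mean_height
        sep = float(np.mod(hi.mean_height - m_lo, self.box.Lz))
        return float(np.mod(m_lo + sep / 2.0, self.box.Lz))

    def locate(self, positions: np.ndarray) -> np.ndarray:
        """Compartment label of each (x, y, z) position (vectorized).

        The four grid heights are bilinearly interpolated at the exact
        (x, y); the position's z then falls into one of the four cyclic
        intervals along the periodic z axis."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        Lz = self.box.Lz
        h = [g.interpolate(positions[:, 0], positions[:, 1]) for g in self.grids]
        z_off = np.mod(positions[:, 2] - h[0], Lz)
        d0 = np.mod(h[1] - h[0], Lz)
        d1 = np.mod(h[2] - h[1], Lz)
        d2 = np.mod(h[3] - h[2], Lz)
        labels = np.full(positions.shape[0], "external", dtype=object)
        labels[z_off < d0 + d1 + d2] = "bilayer2"
        labels[z_off < d0 + d1] = "internal"
        labels[z_off < d0] = "bilayer1"
        return labels


def compartment_volumes(surfaces: BilayerSurfaces) -> dict:
    return surfaces.compartment_volumes()


def locate_compartment(position, surfaces: BilayerSurfaces) -> str:
    """Compartment of a single position (see :meth:`BilayerSurfaces.locate`)."""
    return str(surfaces.locate(np.asarray(position))[0])


def per_lipid_metrics(surfaces: BilayerSurfaces, lipid_counts: dict) -> dict:
    """Per-lipid areas (nm²) per leaflet side and per-lipid volumes (nm³)
    per bilayer.

    `lipid_counts` maps each leaflet label to its lipid count; bilayer
    counts are the sums of their two leaflets.
    """
    out = {}
    vols = surfaces.compartment_volumes()
    for grid in surfaces.grids:
        n = lipid_counts.get(grid.label, 0)
        if n <= 0:
            raise ValueError(f"non-positive lipid count for {grid.label}")
        out[f"area_per_lipid_{grid.label}"] = surface_area(grid) / n
    for b, (la, lb) in ((1, ("b1_external", "b1_internal")),
                        (2, ("b2_internal", "b2_external"))):
        n = lipid_counts.get(la, 0) + lipid_counts.get(lb, 0)
        if n <= 0:
            raise ValueError(f"non-positive lipid count for bilayer {b}")
        out[f"volume_per_lipid_bilayer{b}"] = vols[f"bilayer{b}"] / n
    return out
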