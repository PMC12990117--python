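"""Synthetic configurations with known ground truth.

Every analysis stage in this package is exercised on configurations built
here rather than on MD output: two stacked DPPC-like bilayers in a periodic
box (so the box contains an *external* aqueous compartment, contiguous
across the periodic z boundary, and an *internal* one between the
bilayers), imidazolium-like cation/anion pairs placed in prescribed
penetration regimes, Brownian walkers with a planted diffusion coefficient,
and Metropolis samples from analytic 1-D potentials under harmonic umbrella
biases.

Leaflet surfaces are sinusoidal with integer period counts per box edge, so
they are exactly periodic and their areas have clean quadrature oracles.
Ground-truth labels (leaflet, compartment, cluster membership) are always
returned as a sidecar table, never encoded in bead names.

No force field is evaluated anywhere; water beads exist on a jittered
lattice only to exercise selection and compartment logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Frame, RoleMap, SimulationBox
from .wham import UmbrellaWindow

logger = logging.getLogger("cgmem")

__all__ = [
    "BilayerSpec",
    "IonPlacement",
    "PotentialSpec",
    "SyntheticSystem",
    "default_role_map",
    "generate_two_bilayer_system",
    "place_ions",
    "brownian_trajectory",
    "sample_umbrella_windows",
]

# Bead naming of the synthetic topology (Martini-like):
#   lipid  "DPPC": PO4 + tails C1A..C4A, C1B..C4B       (9 beads)
#   cation "CAT":  RNG (imidazolium ring) + CT1..CT4    (5 beads)
#   anion  "ANI":  BF4                                  (1 bead)
#   water  "W":    W
LIPID_TAIL_BEADS = [f"C{i}{s}" for s in "AB" for i in range(1, 5)]
CATION_TAIL_BEADS = [f"CT{i}" for i in range(1, 5)]


def default_role_map() -> RoleMap:
    """Role map matching the synthetic topology's bead names."""
    return RoleMap.from_dict(
        {
            "phosphate": [["DPPC", "PO4"]],
            "lipid_tail": [["DPPC", b] for b in LIPID_TAIL_BEADS],
            "cation_head": [["CAT", "RNG"]],
            "cation_tail": [["CAT", b] for b in CATION_TAIL_BEADS],
            "anion": [["ANI", "BF4"]],
            "water": [["W", "W"]],
        }
    )


@dataclass
class BilayerSpec:
    """Geometry of one synthetic bilayer.

    ``undulation_periods`` are integer period counts along x and y, so the
    surface z(x, y) = z0 + A·sin(2π·px·x/Lx)·cos(2π·py·y/Ly) is exactly
    periodic (py = 0 gives a pure x-sinusoid)."""

    n_lipids_per_leaflet: int
    area_per_lipid: float  # nm^2
    thickness: float  # nm, leaflet-sheet separation
    undulation_amplitude: float = 0.0  # nm
    undulation_periods: tuple[int, int] = (1, 0)
    z_center: float = 0.0  # nm

    def __post_init__(self) -> None:
        if self.area_per_lipid <= 0 or self.thickness <= 0:
            raise ValueError("area per lipid and thickness must be positive")
        if self.undulation_amplitude < 0:
            raise ValueError("undulation amplitude must be >= 0")
        px, py = self.undulation_periods
        if px != int(px) or py != int(py):
            raise ValueError("undulation periods must be integers")

    def surface(self, x, y, box: SimulationBox, sign: int) -> np.ndarray:
        """Height of the leaflet sheet at (x, y); sign = +1 upper, -1 lower."""
        px, py = self.undulation_periods
        und = self.undulation_amplitude * np.sin(2 * np.pi * px * np.asarray(x) / box.Lx)
        und = und * np.cos(2 * np.pi * py * np.asarray(y) / box.Ly)
        return self.z_center + sign * self.thickness / 2.0 + und


@dataclass
class IonPlacement:
    """How many ion pairs to insert and in which penetration regime."""

    n_pairs: int
    mode: str = "dispersed_external"
    cluster_radius: float = 2.0  # nm, micelle / core_droplet only
    n_tail_beads: int = 4

    MODES = (
        "dispersed_external",
        "micelle",
        "interfacial",
        "core_droplet",
        "internal_solution",
    )

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.mode not in self.MODES:
            raise ValueError(f"unknown placement mode {self.mode!r}")


@dataclass
class PotentialSpec:
    """Analytic 1-D potential U(ξ), kJ/mol, used as a WHAM test oracle.

    forms:
      flat             U = 0
      harmonic         U = ½·kappa·(ξ−x0)²          params: kappa, x0
      double_well      U = h·((ξ−x0)²/a² − 1)²      params: h (barrier), a, x0
      gaussian_barrier U = A·exp(−(ξ−x0)²/(2σ²))    params: A, sigma, x0
    """

    form: str = "flat"
    params: dict = field(default_factory=dict)

    def __call__(self, xi):
        xi = np.asarray(xi, dtype=float)
        p = self.params
        x0 = p.get("x0", 0.0)
        if self.form == "flat":
            return np.zeros_like(xi)
        if self.form == "harmonic":
            return 0.5 * p["kappa"] * (xi - x0) ** 2
        if self.form == "double_well":
            return p["h"] * ((xi - x0) ** 2 / p["a"] ** 2 - 1.0) ** 2
        if self.form == "gaussian_barrier":
            return p["A"] * np.exp(-((xi - x0) ** 2) / (2 * p["sigma"] ** 2))
        raise ValueError(f"unknown potential form {self.form!r}")


class PackingError(ValueError):
    """Requested contents do not fit the box / compartment."""


# ---------------------------------------------------------------------------
# Two-bilayer construction
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSystem:
    """A generated frame plus its out-of-band ground truth.

    ``truth`` has one row per molecule: molecule_id, species
    (lipid/water/cation/anion), label (leaflet label for lipids,
    compartment for everything else) and cluster (aggregate id, -1 for
    unclustered)."""

    frame: Frame
    truth: pd.DataFrame
    specs: tuple[BilayerSpec, BilayerSpec]

    @property
    def box(self) -> SimulationBox:
        return self.frame.box

    def midplane(self, bilayer: int) -> float:
        return self.specs[bilayer - 1].z_center

    def compartment_of_z(self, z: float) -> str:
        """Compartment of a z coordinate under the *construction* geometry
        (flat reference sheets; used for placement, not analysis)."""
        s1, s2 = self.specs
        lo1, hi1 = s1.z_center - s1.thickness / 2, s1.z_center + s1.thickness / 2
        lo2, hi2 = s2.z_center - s2.thickness / 2, s2.z_center + s2.thickness / 2
        z = z % self.box.Lz
        if lo1 <= z <= hi1:
            return "bilayer1"
        if lo2 <= z <= hi2:
            return "bilayer2"
        if hi1 < z < lo2:
            return "internal"
        return "external"


def _leaflet_lattice(n: int, box: SimulationBox, rng, jitter: float):
    """Quasi-uniform (x, y) sites for n lipids with lateral jitter."""
    nx = int(np.ceil(np.sqrt(n * box.Lx / box.Ly)))
    ny = int(np.ceil(n / nx))
    xs = (np.arange(nx) + 0.5) * box.Lx / nx
    ys = (np.arange(ny) + 0.5) * box.Ly / ny
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])[:n]
    pts += rng.uniform(-jitter, jitter, size=pts.shape)
    pts[:, 0] %= box.Lx
    pts[:, 1] %= box.Ly
    return pts


def generate_two_bilayer_system(
    spec1: BilayerSpec,
    spec2: BilayerSpec,
    box: SimulationBox,
    seed: int,
    water_density: float = 1.5,
    lateral_jitter: float = 0.05,
    z_jitter: float = 0.0,
) -> SyntheticSystem:
    """Build a frame with two stacked bilayers plus water in both aqueous
    compartments.

    Each lipid is one phosphate bead on its leaflet sheet and two 4-bead
    tails pointing toward the bilayer midplane.  Phosphate sheets sit at
    z_center ± thickness/2 plus the undulation term.  Water beads occupy a
    jittered lattice at `water_density` beads/nm³ in the external and
    internal compartments only, with a 0.3 nm standoff from the (possibly
    undulated) phosphate sheets; none fall between a bilayer's two sheets.
    Deterministic for a fixed seed.

    Raises :class:`PackingError` when the lipid lattice does not fit the
    box at the stated area per lipid (n·apl must equal Lx·Ly within 1%).
    """
    rng = np.random.default_rng(seed)
    if spec2.z_center <= spec1.z_center:
        raise ValueError("spec2 must sit above spec1 along z")
    for spec in (spec1, spec2):
        target = spec.n_lipids_per_leaflet * spec.area_per_lipid
        if abs(target - box.Lx * box.Ly) > 0.01 * box.Lx * box.Ly:
            raise PackingError(
                f"{spec.n_lipids_per_leaflet} lipids at {spec.area_per_lipid} "
                f"nm² occupy {target:.2f} nm², box cross-section is "
                f"{box.Lx * box.Ly:.2f} nm²"
            )

    mol_ids, res, bead, pos = [], [], [], []
    truth_rows = []
    next_mol = 1

    leaflet_labels = {
        (1, -1): "b1_external",
        (1, +1): "b1_internal",
        (2, -1): "b2_internal",
        (2, +1): "b2_external",
    }
    for b_index, spec in ((1, spec1), (2, spec2)):
        for sign in (-1, +1):
            label = leaflet_labels[(b_index, sign)]
            sites = _leaflet_lattice(spec.n_lipids_per_leaflet, box, rng, lateral_jitter)
            z_surf = spec.surface(sites[:, 0], sites[:, 1], box, sign)
            if z_jitter > 0:
                z_surf = z_surf + rng.uniform(-z_jitter, z_jitter, size=z_surf.shape)
            # tails step from the sheet toward the midplane, staying inside
            tail_step = (spec.thickness / 2.0) / 5.0
            for i in range(spec.n_lipids_per_leaflet):
                x, y, zp = sites[i, 0], sites[i, 1], z_surf[i]
                mol = next_mol
                next_mol += 1
                mol_ids.append(mol); res.append("DPPC"); bead.append("PO4")
                pos.append((x, y, zp))
                for t, chain_dx in (("A", -0.12), ("B", +0.12)):
                    for kb in range(1, 5):
                        mol_ids.append(mol); res.append("DPPC")
                        bead.append(f"C{kb}{t}")
                        pos.append(
                            ((x + chain_dx) % box.Lx, y, zp - sign * kb * tail_step)
                        )
                truth_rows.append((mol, "lipid", label, -1))

    # water: jittered lattice, compartment-aware with undulation standoff
    margin = 0.3
    n_cells = max(1, int(round((water_density * box.volume) ** (1 / 3))))
    spacing = (box.volume / n_cells**3) ** (1 / 3)
    axes = [np.arange(spacing / 2, L, spacing) for L in box.lengths]
    WX, WY, WZ = np.meshgrid(*axes, indexing="ij")
    wpts = np.column_stack([WX.ravel(), WY.ravel(), WZ.ravel()])
    wpts += rng.uniform(-0.3 * spacing, 0.3 * spacing, size=wpts.shape)
    wpts %= box.lengths

    keep = np.ones(len(wpts), dtype=bool)
    comp = np.empty(len(wpts), dtype=object)
    for b_spec in (spec1, spec2):
        lo = b_spec.surface(wpts[:, 0], wpts[:, 1], box, -1) - margin
        hi = b_spec.surface(wpts[:, 0], wpts[:, 1], box, +1) + margin
        keep &= ~((wpts[:, 2] >= lo) & (wpts[:, 2] <= hi))
    hi1 = spec1.surface(wpts[:, 0], wpts[:, 1], box, +1)
    lo2 = spec2.surface(wpts[:, 0], wpts[:, 1], box, -1)
    comp[(wpts[:, 2] > hi1) & (wpts[:, 2] < lo2)] = "internal"
    comp[comp == None] = "external"  # noqa: E711

    for p, c in zip(wpts[keep], comp[keep]):
        mol = next_mol
        next_mol += 1
        mol_ids.append(mol); res.append("W"); bead.append("W")
        pos.append(tuple(p))
        truth_rows.append((mol, "water", c, -1))

    frame = Frame(
        0.0,
        box,
        np.array(mol_ids),
        np.array(res, dtype=object),
        np.array(bead, dtype=object),
        np.array(pos, dtype=float),
    ).wrapped()
    truth = pd.DataFrame(
        truth_rows, columns=["molecule_id", "species", "label", "cluster"]
    )
    return SyntheticSystem(frame, truth, (spec1, spec2))


# ---------------------------------------------------------------------------
# Ion placement
# ---------------------------------------------------------------------------

def _external_z_interval(system: SyntheticSystem, margin: float):
    """(z_lo, z_hi) of the external slab, expressed as a contiguous
    interval above bilayer 2 wrapping to below bilayer 1."""
    s1, s2 = system.specs
    amp1 = s1.undulation_amplitude
    amp2 = s2.undulation_amplitude
    lo = s2.z_center + s2.thickness / 2 + amp2 + margin
    hi = s1.z_center - s1.thickness / 2 - amp1 - margin + system.box.Lz
    if hi <= lo:
        raise PackingError("external compartment too thin for placement")
    return lo, hi


def _internal_z_interval(system: SyntheticSystem, margin: float):
    s1, s2 = system.specs
    lo = s1.z_center + s1.thickness / 2 + s1.undulation_amplitude + margin
    hi = s2.z_center - s2.thickness / 2 - s2.undulation_amplitude - margin
    if hi <= lo:
        raise PackingError("internal compartment too thin for placement")
    return lo, hi


def _cation_beads(head_pos, direction, n_tail, bond=0.3):
    """Head + tail bead positions of one cation chain along `direction`."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    beads = [np.asarray(head_pos, dtype=float)]
    for k in range(1, n_tail + 1):
        beads.append(beads[0] + u * bond * k)
    return np.array(beads)


def _random_unit(rng, n=None):
    v = rng.normal(size=(n, 3) if n else 3)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _scatter_separated(rng, n, z_lo, z_hi, box, min_sep=1.0, max_tries=20000):
    """Random points in the slab z∈[z_lo, z_hi] (mod Lz) with pairwise
    separation > min_sep under the minimum image."""
    pts: list[np.ndarray] = []
    L = box.lengths
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"could not place {n} ions with {min_sep} nm separation"
            )
        cand = np.array(
            [
                rng.uniform(0, box.Lx),
                rng.uniform(0, box.Ly),
                rng.uniform(z_lo, z_hi) % box.Lz,
            ]
        )
        ok = True
        for p in pts:
            d = cand - p
            d -= L * np.round(d / L)
            if np.linalg.norm(d) <= min_sep:
                ok = False
                break
        if ok:
            pts.append(cand)
    return np.array(pts)


def place_ions(
    system: SyntheticSystem, placement: IonPlacement, seed: int
) -> SyntheticSystem:
    """Insert cation/anion pairs into a generated two-bilayer system.

    Regimes mirror the penetration stages of imidazolium ionic liquids:
    isolated solvated ions (``dispersed_external``, pairwise molecule
    separations > 1 nm), self-assembled aggregates in solution
    (``micelle``), cations adsorbed on the outer leaflets
    (``interfacial``), an aggregate lodged at the first bilayer's midplane
    (``core_droplet``), and ions dispersed in the internal compartment
    (``internal_solution``).

    For micelle/core_droplet every cation tail bead lies within
    ``cluster_radius`` of the common center, and the innermost tail beads
    are packed within 0.3 nm of it so the aggregate is a single connected
    component at any contact cutoff ≥ 0.6 nm.  Ground-truth compartment
    and cluster labels are appended to the sidecar table.
    """
    if placement.n_pairs == 0:
        return system
    rng = np.random.default_rng(seed)
    box = system.box
    n = placement.n_pairs
    nt = placement.n_tail_beads

    frame = system.frame
    mol_ids = list(frame.molecule_ids)
    res = list(frame.residue_names)
    bead = list(frame.bead_names)
    pos = list(frame.positions)
    truth_rows = []
    next_mol = int(frame.molecule_ids.max()) + 1 if frame.n_beads else 1

    def add_cation(beads_xyz, compartment, cluster):
        nonlocal next_mol
        mol = next_mol
        next_mol += 1
        names = ["RNG"] + CATION_TAIL_BEADS[:nt]
        for nm, p in zip(names, beads_xyz):
            mol_ids.append(mol); res.append("CAT"); bead.append(nm)
            pos.append(np.mod(p, box.lengths))
        truth_rows.append((mol, "cation", compartment, cluster))

    def add_anion(p, compartment):
        nonlocal next_mol
        mol = next_mol
        next_mol += 1
        mol_ids.append(mol); res.append("ANI"); bead.append("BF4")
        pos.append(np.mod(p, box.lengths))
        truth_rows.append((mol, "anion", compartment, -1))

    mode = placement.mode
    chain_len = 0.3 * nt

    if mode in ("dispersed_external", "internal_solution"):
        # xy lattice with spacing > 1 nm and all cation chains along +z:
        # lateral separation alone then guarantees > 1 nm between any two
        # molecules, whatever their z
        comp = "external" if mode == "dispersed_external" else "internal"
        z_lo, z_hi = (
            _external_z_interval(system, margin=0.4)
            if comp == "external"
            else _internal_z_interval(system, margin=0.4)
        )
        if z_hi - z_lo < chain_len + 0.1:
            raise PackingError(f"{comp} compartment too thin for ion chains")
        m = int(np.ceil(np.sqrt(2 * n)))
        sx, sy = box.Lx / m, box.Ly / m
        if min(sx, sy) <= 1.05:
            raise PackingError(
                f"cannot disperse {n} ion pairs with > 1 nm separation in a "
                f"{box.Lx:.1f} x {box.Ly:.1f} nm cross-section"
            )
        jitter = min(0.45 * (min(sx, sy) - 1.0), 0.25)
        gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        sites = np.column_stack([(gx.ravel() + 0.5) * sx, (gy.ravel() + 0.5) * sy])
        order = rng.permutation(len(sites))[: 2 * n]
        sites = sites[order] + rng.uniform(-jitter, jitter, size=(2 * n, 2))
        zvals = rng.uniform(z_lo, z_hi - chain_len, size=2 * n) % box.Lz
        for i in range(n):
            head = np.array([sites[i, 0], sites[i, 1], zvals[i]])
            add_cation(_cation_beads(head, (0, 0, 1), nt), comp, -1)
        for i in range(n, 2 * n):
            add_anion(np.array([sites[i, 0], sites[i, 1], zvals[i]]), comp)

    elif mode in ("micelle", "core_droplet"):
        rad = placement.cluster_radius
        if rad <= 0.4:
            raise PackingError("cluster radius too small for a tail chain")
        if mode == "core_droplet":
            center = np.array([box.Lx / 2, box.Ly / 2, system.midplane(1)])
            comp = "bilayer1"
        else:
            lo, hi = _external_z_interval(system, margin=rad + 0.5)
            center = np.array(
                [rng.uniform(0, box.Lx), rng.uniform(0, box.Ly),
                 rng.uniform(lo, hi) % box.Lz]
            )
            comp = "external"
        # tails radial: innermost bead within 0.3 nm of center, outermost
        # within cluster_radius; head just beyond the outermost tail bead
        r_in = 0.3 * rng.uniform(0.0, 1.0, size=n) ** (1 / 3)
        span = min(rad - 0.05, chain_len) - 0.0
        dirs = _random_unit(rng, n)
        for i in range(n):
            u = dirs[i]
            step = max((span - r_in[i]) / max(nt - 1, 1), 0.05)
            tail = [center + u * (r_in[i] + k * step) for k in range(nt)]
            head = center + u * (r_in[i] + nt * step)
            add_cation(np.array([head] + tail), comp, 0)
        # anions shell just outside the aggregate
        for i in range(n):
            u = _random_unit(rng)
            add_anion(center + u * (rad + 0.5 + 0.3 * rng.uniform()), comp)

    elif mode == "interfacial":
        s1 = system.specs[0]
        sites = _leaflet_lattice(n, box, rng, 0.1)
        z = s1.surface(sites[:, 0], sites[:, 1], box, -1)
        for i in range(n):
            head = np.array([sites[i, 0], sites[i, 1], z[i] - 0.2])
            add_cation(_cation_beads(head, (0, 0, -1), nt), "external", -1)
        lo, hi = _external_z_interval(system, margin=0.5)
        for p in _scatter_separated(rng, n, lo, hi, box, min_sep=0.8):
            add_anion(p, "external")

    new_frame = Frame(
        frame.time,
        box,
        np.array(mol_ids),
        np.array(res, dtype=object),
        np.array(bead, dtype=object),
        np.array(pos, dtype=float),
    )
    truth = pd.concat(
        [
            system.truth,
            pd.DataFrame(
                truth_rows, columns=["molecule_id", "species", "label", "cluster"]
            ),
        ],
        ignore_index=True,
    )
    return SyntheticSystem(new_frame, truth, system.specs)


# ---------------------------------------------------------------------------
# Brownian walkers
# ---------------------------------------------------------------------------

def brownian_trajectory(
    n_particles: int,
    D: float,
    dt: float,
    n_steps: int,
    box: SimulationBox,
    seed: int,
):
    """Free Brownian walkers: per-step per-axis displacements are i.i.d.
    Gaussian with variance 2·D·dt.

    Returns ``(frames, unwrapped)`` — a list of wrapped :class:`Frame`
    objects and the ground-truth unwrapped coordinates with shape
    ``(n_steps + 1, n_particles, 3)``.
    """
    if D < 0 or dt <= 0:
        raise ValueError("need D >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, 1.0, size=(n_particles, 3)) * box.lengths
    steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(n_steps, n_particles, 3))
    unwrapped = np.empty((n_steps + 1, n_particles, 3))
    unwrapped[0] = start
    np.cumsum(steps, axis=0, out=unwrapped[1:])
    unwrapped[1:] += start

    ids = np.arange(1, n_particles + 1)
    res = np.array(["ION"] * n_particles, dtype=object)
    names = np.array(["ION"] * n_particles, dtype=object)
    frames = [
        Frame(i * dt, box, ids, res, names, np.mod(unwrapped[i], box.lengths))
        for i in range(n_steps + 1)
    ]
    return frames, unwrapped


# ---------------------------------------------------------------------------
# Umbrella sampling from analytic potentials
# ---------------------------------------------------------------------------

class SamplingError(RuntimeError):
    pass


def sample_umbrella_windows(
    potential: PotentialSpec,
    window_centers,
    k: float,
    n_samples: int,
    kT: float,
    seed: int,
    burn_in: int = 1000,
    step_size: float | None = None,
) -> list[UmbrellaWindow]:
    """Metropolis samples from ρ_j(ξ) ∝ exp(−[U(ξ) + ½k(ξ−ξ_j)²]/kT).

    One independent chain per window, started at the window center, with
    Gaussian proposals of width `step_size` (default √(kT/k), near-optimal
    when the bias dominates).  `burn_in` draws are discarded.  Acceptance
    rates are logged; zero acceptance after burn-in raises
    :class:`SamplingError` with diagnostics.
    """
    if k <= 0 or kT <= 0:
        raise ValueError("need k > 0 and kT > 0")
    rng = np.random.default_rng(seed)
    if step_size is None:
        step_size = float(np.sqrt(kT / k))
    windows = []
    for center in window_centers:
        def energy(xi, c=center):
            return float(potential(xi)) + 0.5 * k * (xi - c) ** 2

        xi = float(center)
        e = energy(xi)
        total = n_samples + burn_in
        props = rng.normal(0.0, step_size, size=total)
        us = rng.uniform(size=total)
        out = np.empty(n_samples)
        accepted = 0
        for t in range(total):
            cand = xi + props[t]
            e_cand = energy(cand)
            if e_cand <= e or us[t] < np.exp(-(e_cand - e) / kT):
                xi, e = cand, e_cand
                if t >= burn_in:
                    accepted += 1
            if t >= burn_in:
                out[t - burn_in] = xi
        rate = accepted / n_samples
        logger.debug("window ξ=%.3f: acceptance %.2f", center, rate)
        if rate == 0.0:
            raise SamplingError(
                f"window ξ={center}: zero acceptance after burn-in "
                f"(step={step_size:.4g}, kT={kT:.4g})"
            )
        windows.append(UmbrellaWindow(float(center), k, out))
    return windows
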