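"""Umbrella-sampling free-energy analysis: WHAM, bootstrap errors, ΔG
summaries and chain-length regression.

The potential of mean force G(ξ) along a 1-D reaction coordinate ξ (here
the distance of a cation head group from the bilayer center, in nm) is
reconstructed from harmonically biased windows by solving the standard
weighted-histogram (WHAM) self-consistency equations:

    p_b = Σ_j n_j(b)  /  Σ_j N_j exp((F_j - w_j(ξ_b)) / kT)
    F_j = -kT ln Σ_b p_b exp(-w_j(ξ_b) / kT)

with w_j(ξ) = ½ k_j (ξ - ξ_j)² the bias of window j, n_j(b) its histogram
count in bin b and N_j its sample count.  G(ξ_b) = -kT ln p_b, shifted so
that G vanishes at a reference coordinate (by default ξ = 4.5 nm, the
aqueous solution).

Statistical errors follow the block-bootstrap scheme of splitting each
window's time series into contiguous blocks, recomputing one PMF per block
and taking the per-bin standard deviation across the block PMFs.

Energies are kJ/mol throughout; kT defaults to R·T at 309 K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.special import logsumexp

logger = logging.getLogger("cgmem")

#: Molar gas constant, kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 0.0083145

#: Default temperature (K) and thermal energy (kJ/mol).
DEFAULT_T = 309.0


def thermal_energy(T: float = DEFAULT_T) -> float:
    """kT in kJ/mol at temperature T (K)."""
    return R_KJ_PER_MOL_K * T


class WhamConvergenceError(RuntimeError):
    pass


class WindowGapError(ValueError):
    """Umbrella windows do not chain with pairwise overlap along ξ."""


@dataclass
class UmbrellaWindow:
    """One umbrella window: bias center (nm), force constant
    (kJ mol⁻¹ nm⁻²) and the sampled ξ time series (nm)."""

    center: float
    k: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("force constant must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D series")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite sample")

    def bias(self, xi: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(xi) - self.center) ** 2


@dataclass
class PMFCurve:
    """Binned free-energy profile.  Bins with no samples carry NaN (never
    imputed)."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    stderr: np.ndarray | None
    kT: float
    xi_ref: float

    def value_at(self, xi: float) -> float:
        """Free energy at the bin nearest to ξ (NaN-checked)."""
        i = int(np.argmin(np.abs(self.bin_centers - xi)))
        g = self.free_energy[i]
        if not np.isfinite(g):
            raise ValueError(f"PMF undefined at ξ={xi} (empty bin)")
        return float(g)


@dataclass
class DeltaGSummary:
    """Free-energy drops from aqueous solution into the bilayer.

    ``barrier`` is the cost of moving from the PMF global minimum to the
    bilayer center: ΔG(water→center) − ΔG(water→min)."""

    dg_water_to_min: float
    dg_water_to_center: float
    barrier: float
    xi_min: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


# ---------------------------------------------------------------------------
# WHAM core
# ---------------------------------------------------------------------------

def _check_overlap(windows: list[UmbrellaWindow]) -> None:
    order = np.argsort([w.center for w in windows])
    spans = []
    for i in order:
        s = windows[i].samples
        spans.append((s.min(), s.max()))
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if lo2 > hi1:
            logger.warning(
                "umbrella windows leave a sampling gap (%.3f, %.3f) nm",
                hi1, lo2,
            )


def wham(
    windows: list[UmbrellaWindow],
    bin_edges: np.ndarray,
    kT: float = thermal_energy(),
    tol: float = 1e-7,
    max_iter: int = 100_000,
    xi_ref: float = 4.5,
) -> PMFCurve:
    """Solve the WHAM equations on the given ξ bins.

    Raises :class:`WhamConvergenceError` if max|ΔF_j| has not dropped below
    `tol` (kJ/mol) after `max_iter` direct iterations.  Empty bins yield
    NaN free energy.  The profile is shifted so G(ξ_ref) = 0, with ξ_ref
    snapped to the nearest populated bin.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    if not windows:
        raise ValueError("no umbrella windows")
    bin_edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    _check_overlap(windows)

    counts_all = np.array(
        [np.histogram(w.samples, bins=bin_edges)[0] for w in windows], dtype=float
    )
    # N_j counts only in-range samples: a sample outside the binned ξ range
    # carries no histogram information (dropping it keeps the likelihood
    # gauge-invariant, Σ_b n_jb = N_j)
    in_range = counts_all.sum(axis=1)
    dropped = np.array([w.samples.size for w in windows]) - in_range
    if dropped.sum():
        logger.info(
            "WHAM: %d samples outside [%g, %g] nm ignored",
            int(dropped.sum()), bin_edges[0], bin_edges[-1],
        )
    keep = in_range > 0
    if not keep.all():
        logger.warning(
            "WHAM: %d windows have no samples in range and are dropped",
            int((~keep).sum()),
        )
    windows = [w for w, k_ in zip(windows, keep) if k_]
    counts = counts_all[keep]
    N = in_range[keep]
    n_win = len(windows)
    total = counts.sum(axis=0)  # Σ_j n_j(b)

    # Bias energy of window j evaluated at bin center b, units of kT.
    w_over_kT = np.array([w.bias(centers) / kT for w in windows])
    logN = np.log(N)

    # The WHAM fixed point maximizes the histogram likelihood; in the free
    # energies f_j = F_j/kT it is the minimum of the convex, gauge-invariant
    #   Φ(f) = Σ_b T_b ln Σ_j N_j exp(f_j − w_jb) − Σ_j N_j f_j .
    # Direct (Picard) iteration of the self-consistency equations stalls
    # when window overlap is weak (stiff biases), so Φ is minimized in the
    # log domain instead; tol is the allowed self-consistency violation
    # max_j |F_j + kT·ln Σ_b p_b exp(−w_jb/kT)| at the solution.
    pop = total > 0  # only populated bins contribute

    def _log_denom(f):
        return logsumexp(logN[:, None] + f[:, None] - w_over_kT[:, pop], axis=0)

    def objective(f):
        ld = _log_denom(f)
        phi = float(np.sum(total[pop] * ld) - np.sum(N * f))
        grad = (
            np.exp(
                logsumexp(
                    np.log(total[pop])[None, :]
                    + logN[:, None]
                    + f[:, None]
                    - w_over_kT[:, pop]
                    - ld[None, :],
                    axis=1,
                )
            )
            - N
        )
        return phi, grad

    trace: list[float] = []

    def _resid(f) -> float:
        ld = _log_denom(f)
        log_p = np.log(total[pop]) - ld
        log_z = logsumexp(log_p[None, :] - w_over_kT[:, pop], axis=1)
        return float(np.max(np.abs(f + log_z))) * kT

    res = minimize(
        objective,
        np.zeros(n_win),
        jac=True,
        method="L-BFGS-B",
        callback=lambda f: trace.append(_resid(f)),
        options={"maxiter": max_iter, "gtol": 1e-14, "ftol": 1e-16},
    )
    f = res.x - res.x[0]
    # polish with damped Newton steps on Φ (gauge fixed at f_0 = 0) —
    # quadratically convergent where L-BFGS's own stopping rules give up
    for _ in range(50):
        resid = _resid(f)
        trace.append(resid)
        if resid < tol:
            break
        ld = _log_denom(f)
        q = np.exp(
            logN[:, None] + f[:, None] - w_over_kT[:, pop] - ld[None, :]
        )  # q_jb: weight of window j in bin b
        grad = q @ total[pop] - N
        H = np.diag(q @ total[pop]) - (q * total[pop]) @ q.T
        step = np.linalg.lstsq(
            H[1:, 1:], -grad[1:], rcond=None
        )[0]
        nrm = np.linalg.norm(step)
        if nrm > 50.0:  # trust region: likelihood is flat far out
            step *= 50.0 / nrm
        f = f.copy()
        f[1:] += step
    resid = _resid(f)
    logger.debug(
        "WHAM: %d L-BFGS iterations, residual trace %s",
        res.nit,
        [f"{r:.2e}" for r in trace[:: max(1, len(trace) // 10)]],
    )
    if resid > tol:
        raise WhamConvergenceError(
            f"WHAM not converged after {res.nit} iterations "
            f"(self-consistency residual {resid:.3e} kJ/mol > tol {tol:g})"
        )

    log_p = np.full(centers.size, np.nan)
    log_p[pop] = np.log(total[pop]) - _log_denom(f)
    G = -kT * log_p

    populated = np.isfinite(G)
    if not populated.any():
        raise ValueError("all bins empty")
    # reference: nearest populated bin to xi_ref
    cand = np.where(populated)[0]
    i_ref = cand[np.argmin(np.abs(centers[cand] - xi_ref))]
    G = G - G[i_ref]
    return PMFCurve(centers, G, None, kT, float(centers[i_ref]))


def bootstrap_pmf(
    windows: list[UmbrellaWindow],
    bin_edges: np.ndarray,
    kT: float = thermal_energy(),
    n_blocks: int = 5,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    xi_ref: float = 4.5,
) -> PMFCurve:
    """WHAM with block-bootstrap errors.

    Each window's time series is cut into `n_blocks` contiguous blocks
    (trailing remainder dropped, logged); one PMF is computed per block
    index and the per-bin standard deviation across those PMFs is reported
    as the error.  Bins empty in any block PMF get NaN stderr.
    """
    for w in windows:
        if w.samples.size < n_blocks:
            raise ValueError(
                f"window at ξ={w.center}: {w.samples.size} samples cannot "
                f"be split into {n_blocks} blocks"
            )
    dropped = sum(w.samples.size % n_blocks for w in windows)
    if dropped:
        logger.info("bootstrap: dropping %d trailing samples", dropped)

    block_curves = []
    for b in range(n_blocks):
        sub = []
        for w in windows:
            m = w.samples.size // n_blocks
            sub.append(UmbrellaWindow(w.center, w.k, w.samples[b * m:(b + 1) * m]))
        block_curves.append(
            wham(sub, bin_edges, kT=kT, tol=tol, max_iter=max_iter, xi_ref=xi_ref)
        )

    full = wham(windows, bin_edges, kT=kT, tol=tol, max_iter=max_iter, xi_ref=xi_ref)
    G_blocks = np.array([c.free_energy for c in block_curves])
    stderr = np.std(G_blocks, axis=0, ddof=1)
    stderr[~np.isfinite(G_blocks).all(axis=0)] = np.nan
    full.stderr = stderr
    return full


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def delta_g(
    pmf: PMFCurve, xi_solution: float = 4.5, xi_center: float = 0.0
) -> DeltaGSummary:
    """ΔG from aqueous solution to the PMF global minimum and to the
    bilayer center (nearest-bin lookups)."""
    g_sol = pmf.value_at(xi_solution)
    g_cen = pmf.value_at(xi_center)
    finite = np.isfinite(pmf.free_energy)
    i_min = int(np.nanargmin(np.where(finite, pmf.free_energy, np.inf)))
    g_min = float(pmf.free_energy[i_min])
    dg_min = g_min - g_sol
    dg_cen = g_cen - g_sol
    return DeltaGSummary(
        dg_water_to_min=dg_min,
        dg_water_to_center=dg_cen,
        barrier=dg_cen - dg_min,
        xi_min=float(pmf.bin_centers[i_min]),
    )


def fit_linear(n_carbons, delta_g_values) -> RegressionResult:
    """OLS of ΔG against alkyl-chain carbon count.

    Used to quantify the hydrophobic free-energy gain per CH₂ group
    (slope, kJ/mol per carbon)."""
    n = np.asarray(n_carbons, dtype=float)
    y = np.asarray(delta_g_values, dtype=float)
    if n.size < 2 or np.unique(n).size < 2:
        raise ValueError("need >= 2 distinct chain lengths")
    res = stats.linregress(n, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


# ---------------------------------------------------------------------------
# Window file I/O (delimited text; header lines start with '#')
# ---------------------------------------------------------------------------

def read_window(path: str | Path) -> UmbrellaWindow:
    """Read one window file: '# center= <nm>  k= <kJ/mol/nm2>' header then
    one ξ sample per line."""
    center = k = None
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].replace("=", " = ").split()
                for key, name in (("center", "center"), ("k", "k")):
                    if key in toks:
                        val = float(toks[toks.index(key) + 2])
                        if name == "center":
                            center = val
                        else:
                            k = val
            else:
                samples.append(float(line.split()[0]))
    if center is None or k is None:
        raise ValueError(f"{path}: missing '# center= ... k= ...' header")
    return UmbrellaWindow(center, k, np.array(samples))


def write_window(window: UmbrellaWindow, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# center= {window.center:.6g} k= {window.k:.6g}\n")
        for s in window.samples:
            fh.write(f"{s:.6f}\n")


def write_pmf(pmf: PMFCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kT= {pmf.kT:.6g} kJ/mol, reference= {pmf.xi_ref:.6g} nm\n")
        fh.write("# xi_nm  G_kJ_per_mol  stderr_kJ_per_mol\n")
        err = pmf.stderr if pmf.stderr is not None else np.full_like(pmf.free_energy, np.nan)
        for x, g, e in zip(pmf.bin_centers, pmf.free_energy, err):
            fh.write(f"{x:.4f} {g:.6f} {e:.6f}\n")
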