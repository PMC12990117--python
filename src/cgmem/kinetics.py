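"""Diffusion and compartment-exchange kinetics.

Mean-squared displacement (MSD) over sliding time origins gives the
diffusion coefficient through the Einstein relation MSD(τ) = 2·d·D·τ, with
d = 2 for lateral (xy) motion — the convention for lipids in a bilayer —
and d = 3 for free ions.  Periodic trajectories are unwrapped first by
accumulating minimum-image frame-to-frame increments.

Unit note: D is computed in nm²/ps and also reported in cm²/s;
1 nm²/ps = 10⁻⁶ m²/s = 10⁻² cm²/s (implemented once, below).

Compartment-resolved concentration series track ion penetration: each
molecule's reference site is assigned per frame (no dwell-time hysteresis)
to external / bilayer1 / internal / bilayer2 via the leaflet surface
grids, and counts convert to mol/L as c = N/(N_A·V), i.e.
1/(0.6022·V[nm³]) mol/L per molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft
from scipy import stats

logger = logging.getLogger("cgmem")

#: multiply a D in nm²/ps by this to get cm²/s
NM2_PER_PS_TO_CM2_PER_S = 1e-2

#: (N_A · 1 nm³) expressed in L/mol: concentration [mol/L] = N / (0.6022·V[nm³])
INV_MOLAR_NM3 = 0.6022


class UndersamplingError(ValueError):
    """Frame spacing too coarse to unwrap unambiguously."""


def unwrap(frames) -> np.ndarray:
    """Accumulate minimum-image increments into continuous coordinates.

    Returns an (n_frames, n_beads, 3) array; rewrapping it into the box
    reproduces the input positions exactly.  Requires every per-frame bead
    displacement below half the box edge; increments at the half-box
    boundary (within 1%) are treated as undersampling and rejected with
    the bead and frame named.
    """
    frames = list(frames)
    if len(frames) < 1:
        raise ValueError("no frames")
    L = frames[0].box.lengths
    out = np.empty((len(frames), frames[0].n_beads, 3))
    out[0] = frames[0].positions
    for t in range(1, len(frames)):
        d = frames[t].positions - frames[t - 1].positions
        d -= L * np.floor(d / L + 0.5)
        near_half = np.abs(d) >= 0.495 * L
        if near_half.any():
            b, ax = np.argwhere(near_half)[0]
            raise UndersamplingError(
                f"bead {b} moves {abs(d[b, ax]):.3f} nm on axis {ax} between "
                f"frames {t - 1} and {t} (≥ half the box edge)"
            )
        out[t] = out[t - 1] + d
    return out


def wrap(unwrapped: np.ndarray, box) -> np.ndarray:
    return np.mod(unwrapped, box.lengths)


@dataclass
class MSDSeries:
    lag_times: np.ndarray  # ps
    msd: np.ndarray  # nm^2
    dims: int
    n_origins: np.ndarray


@dataclass
class DiffusionEstimate:
    D_nm2_per_ps: float
    D_cm2_per_s: float
    fit_range: tuple[float, float]  # ps
    fit_r_squared: float
    dims: int


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Column-wise sliding-origin MSD of a (T, M) array, O(T log T).

    Uses MSD(τ) = S1(τ) − 2·S2(τ): S2 is the autocorrelation (batched
    FFT), S1 comes from prefix sums of the squares."""
    T = x.shape[0]
    n = scipy.fft.next_fast_len(2 * T)
    f = scipy.fft.rfft(x, n=n, axis=0)
    s2 = scipy.fft.irfft(f * np.conj(f), n=n, axis=0)[:T].real
    lags = np.arange(T)
    sq = x * x
    S = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(sq, axis=0)])  # S[i] = Σ sq[:i]
    s1 = S[T - lags] + (S[T] - S[lags])
    return (s1 - 2.0 * s2) / (T - lags)[:, None]


def msd(
    unwrapped: np.ndarray,
    dt: float,
    dims: str = "xyz",
    origin_stride: int = 1,
    max_lag: int | None = None,
) -> MSDSeries:
    """Sliding-origin MSD of unwrapped coordinates (n_frames, n_beads, 3).

    `dims` selects the axes ("xy" for lateral, "xyz" for 3-D).  With
    `origin_stride` 1 (every origin) an FFT algorithm is used; larger
    strides fall back to the direct sum.  MSD(0) = 0 by construction.
    """
    unwrapped = np.asarray(unwrapped, dtype=float)
    if unwrapped.ndim != 3 or unwrapped.shape[0] < 2:
        raise ValueError("need (n_frames >= 2, n_beads, 3) unwrapped coordinates")
    ax = {"x": 0, "y": 1, "z": 2}
    cols = [ax[c] for c in dims]
    T = unwrapped.shape[0]
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)

    if origin_stride == 1:
        n_beads = unwrapped.shape[1]
        acc = np.zeros(T)
        # chunk the (bead, axis) columns to bound FFT workspace memory
        flat = unwrapped[:, :, cols].reshape(T, -1)
        chunk = max(1, int(2e7 // T))
        for s in range(0, flat.shape[1], chunk):
            acc += _msd_fft(flat[:, s:s + chunk]).sum(axis=1)
        vals = acc[: max_lag + 1] / n_beads
        n_origins = (T - np.arange(max_lag + 1)) * n_beads
    else:
        vals = np.zeros(max_lag + 1)
        n_origins = np.zeros(max_lag + 1, dtype=int)
        sub = unwrapped[:, :, cols]
        for lag in range(1, max_lag + 1):
            disp = sub[lag:] - sub[:-lag]
            disp = disp[::origin_stride]
            vals[lag] = np.mean(np.sum(disp**2, axis=-1))
            n_origins[lag] = disp.shape[0] * disp.shape[1]
        n_origins[0] = T * unwrapped.shape[1]
    vals[0] = 0.0
    lags = np.arange(max_lag + 1) * dt
    return MSDSeries(lags, np.maximum(vals, 0.0), len(cols), n_origins)


def diffusion_coefficient(
    series: MSDSeries, fit_fraction: tuple[float, float] = (0.1, 0.5)
) -> DiffusionEstimate:
    """Einstein-relation fit D = slope/(2·d) over a lag window.

    The default window, 10–50% of the maximum lag, skips the short-time
    regime and the poorly averaged tail."""
    t_max = series.lag_times[-1]
    lo, hi = fit_fraction[0] * t_max, fit_fraction[1] * t_max
    m = (series.lag_times >= lo) & (series.lag_times <= hi)
    if m.sum() < 3:
        raise ValueError("fewer than 3 MSD points in the fit range")
    res = stats.linregress(series.lag_times[m], series.msd[m])
    D = float(res.slope) / (2 * series.dims)
    return DiffusionEstimate(
        D_nm2_per_ps=D,
        D_cm2_per_s=D * NM2_PER_PS_TO_CM2_PER_S,
        fit_range=(float(lo), float(hi)),
        fit_r_squared=float(res.rvalue**2),
        dims=series.dims,
    )


# ---------------------------------------------------------------------------
# Compartment concentration series
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationSeries:
    """Per-compartment molecule counts and concentrations over time.

    ``concentrations`` carries the running-mean-smoothed series (mol/L);
    ``concentrations_raw`` the unsmoothed one.  Counts sum to the group
    size in every frame."""

    times_ns: np.ndarray
    counts: pd.DataFrame
    concentrations: pd.DataFrame
    concentrations_raw: pd.DataFrame
    smoothing_frames: int


def concentration_mol_per_L(count: float, volume_nm3: float) -> float:
    """N molecules in V nm³ → mol/L (one molecule in 1.6606 nm³ is 1 M)."""
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    return count / (INV_MOLAR_NM3 * volume_nm3)


def compartment_series(
    frames,
    surfaces_per_frame,
    site_fn,
    smoothing_frames: int = 12,
) -> ConcentrationSeries:
    """Track a group's per-compartment counts and concentrations per frame.

    Each molecule's reference site (`site_fn(frame) -> (M, 3)`, e.g. the
    anion bead or the imidazolium-ring centroid) is located in one of the
    four compartments using that frame's leaflet surfaces; concentrations
    divide by the frame's compartment volume.  A centered running mean of
    `smoothing_frames` frames is applied to the reported concentrations.
    """
    from .profiles import running_mean

    frames = list(frames)
    comps = ("external", "bilayer1", "internal", "bilayer2")
    rows_counts, rows_conc, times = [], [], []
    for i, (frame, surfaces) in enumerate(zip(frames, surfaces_per_frame)):
        sites = site_fn(frame)
        labels = surfaces.locate(sites) if len(sites) else np.array([], dtype=object)
        vols = surfaces.compartment_volumes()
        cnt = {c: int(np.sum(labels == c)) for c in comps}
        if sum(cnt.values()) != len(sites):
            raise RuntimeError(f"frame {i}: compartment counts do not conserve")
        rows_counts.append(cnt)
        rows_conc.append(
            {c: concentration_mol_per_L(cnt[c], vols[c]) for c in comps}
        )
        times.append(frame.time)
    counts = pd.DataFrame(rows_counts)
    conc_raw = pd.DataFrame(rows_conc)
    conc = conc_raw.apply(
        lambda col: running_mean(col.to_numpy(), smoothing_frames), axis=0
    )
    return ConcentrationSeries(
        np.asarray(times, dtype=float) / 1000.0,  # ps -> ns
        counts,
        pd.DataFrame(conc, columns=conc_raw.columns),
        conc_raw,
        smoothing_frames,
    )
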