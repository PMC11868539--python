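"""Blocked fluctuation statistics, spectra and effective-temperature fits.

The fluctuation observables follow the experimental protocol: vertex and
edge time series are cut into non-overlapping 60-s blocks, each
re-centred on its own mean to suppress slow drift; displacement
amplitudes, edge-length deviations L - Lbar and their standard
deviations are computed on the blocked data.  Power spectra, by
contrast, are estimated on the full (linearly detrended) track, because
the sub-mHz corner frequency of the junction dynamics cannot be resolved
inside a 60-s window.

The spectral model is the one-sided Ornstein-Uhlenbeck spectrum of an
overdamped junction in a harmonic trap,

    S(f) = 4 kB Teff / b / [(2 pi)^2 (f^2 + f0^2)]   (m^2/Hz, f in Hz),

with drag b, corner frequency f0 = k / (2 pi b) and effective
temperature Teff.  A single spectrum constrains only (Teff/b, f0), so
the fit comes in two flavours mirroring the paired experimental design:
"passive" fixes Teff = T (heat-killed control) and returns b; "active"
fixes b (from the passive fit) and returns Teff/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .foam_geometry import KB, T_AMBIENT
from .image_analysis import VertexTrack


class FitError(RuntimeError):
    """Spectral fit failed to converge; message carries diagnostics."""


# ---------------------------------------------------------------------------
# Blocking
# ---------------------------------------------------------------------------


@dataclass
class BlockedSeries:
    """Equal-duration, non-overlapping blocks, each re-centred on its mean.

    ``data`` has shape (n_blocks, samples_per_block, d); ``times`` the
    matching sample times.
    """

    source_id: int
    block_s: float
    data: np.ndarray
    times: np.ndarray

    @property
    def n_blocks(self) -> int:
        return self.data.shape[0]


def block_series(track, block_s: float = 60.0, times=None, source_id: int = 0) -> BlockedSeries:
    """Partition a track into re-centred 60-s blocks.

    ``track`` is a :class:`VertexTrack` (both coordinates re-centred) or a
    plain array with explicit ``times``.  The incomplete trailing block is
    dropped.  Raises if the record is shorter than one block.
    """
    if isinstance(track, VertexTrack):
        values = track.positions
        times = track.times
        source_id = track.vertex_id
    else:
        values = np.asarray(track, dtype=float)
        if times is None:
            raise ValueError("explicit times required for array input")
        times = np.asarray(times, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    dt = float(np.median(np.diff(times)))
    per_block = int(round(block_s / dt))
    n_blocks = len(times) // per_block
    if n_blocks < 1:
        raise ValueError(
            f"track of {times[-1] - times[0] + dt:.1f} s is shorter than one {block_s:.0f}-s block"
        )
    n = n_blocks * per_block
    data = values[:n].reshape(n_blocks, per_block, values.shape[1])
    data = data - data.mean(axis=1, keepdims=True)
    return BlockedSeries(source_id, block_s, data, times[:n].reshape(n_blocks, per_block))


# ---------------------------------------------------------------------------
# Displacement and edge statistics
# ---------------------------------------------------------------------------


@dataclass
class DisplacementStats:
    """Summary fluctuation amplitudes of one junction (µm).

    ``max_block_sd`` is the largest per-block rms radial displacement
    (the fluctuation-map statistic); ``mean_distance`` the average radial
    distance from the block centre (the occupancy-model statistic).
    """

    max_block_sd: float
    mean_distance: float


def vertex_displacement_stats(blocked: BlockedSeries) -> DisplacementStats:
    r = np.linalg.norm(blocked.data, axis=2)
    block_sd = np.sqrt((r**2).mean(axis=1))
    return DisplacementStats(float(block_sd.max()), float(r.mean()))


def displacement_from_reference(track: VertexTrack, reference, how: str = "mean_position") -> float:
    """Displacement (µm) of a track from a fixed reference position.

    ``how="mean_position"`` (default) returns |time-averaged position -
    reference|, which averages the fluctuations out and isolates the
    static offset; ``how="mean_distance"`` returns the mean radial
    distance, which includes the fluctuation amplitude as a noise floor.
    """
    ref = np.asarray(reference, dtype=float)
    p = track.positions[track.valid]
    if how == "mean_position":
        return float(np.linalg.norm(p.mean(axis=0) - ref))
    if how == "mean_distance":
        return float(np.linalg.norm(p - ref, axis=1).mean())
    raise ValueError("how must be 'mean_position' or 'mean_distance'")


def displacement_vector_from_reference(track: VertexTrack, reference) -> np.ndarray:
    """Time-averaged displacement vector (µm) from a reference position."""
    ref = np.asarray(reference, dtype=float)
    return track.positions[track.valid].mean(axis=0) - ref


def edge_length_series(track_a: VertexTrack, track_b: VertexTrack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, lengths, valid) of the edge between two tracked junctions."""
    if len(track_a) != len(track_b) or not np.allclose(track_a.times, track_b.times):
        raise ValueError("endpoint tracks must share a common clock")
    L = np.linalg.norm(track_a.positions - track_b.positions, axis=1)
    return track_a.times, L, track_a.valid & track_b.valid


def edge_deviation(
    lengths,
    times,
    valid=None,
    block_s: float = 60.0,
    min_valid: int = 10,
) -> tuple[np.ndarray, float]:
    """Pooled edge-length deviations L - Lbar and their standard deviation.

    Lbar is the per-60-s-block mean over valid frames; blocks with fewer
    than ``min_valid`` valid frames are skipped.  Returns (samples, sd).
    """
    lengths = np.asarray(lengths, dtype=float)
    times = np.asarray(times, dtype=float)
    valid = np.ones(len(lengths), bool) if valid is None else np.asarray(valid, bool)
    dt = float(np.median(np.diff(times)))
    per_block = int(round(block_s / dt))
    n_blocks = len(lengths) // per_block
    samples = []
    for i in range(n_blocks):
        sl = slice(i * per_block, (i + 1) * per_block)
        v = valid[sl]
        if v.sum() < min_valid:
            continue
        L = lengths[sl][v]
        samples.append(L - L.mean())
    if not samples:
        return np.empty(0), float("nan")
    pooled = np.concatenate(samples)
    return pooled, float(pooled.std())


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def estimate_psd(
    track,
    fs: float | None = None,
    detrend: str = "linear",
    window: str = "hann",
    nperseg: int | None = None,
    mode: str = "radial",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density of a junction track.

    For a 2D track the default "radial" mode sums the x and y spectra
    (variances add), so the integral of the PSD equals the total 2D
    displacement variance; ``mode="x"`` or ``"y"`` select one axis.
    Returns (frequencies Hz, PSD µm²/Hz) with the zero bin dropped.
    Uniform sampling is required.
    """
    if isinstance(track, VertexTrack):
        values = track.positions
        dts = np.diff(track.times)
        if np.ptp(dts) > 1e-9 * np.median(dts):
            raise ValueError("PSD requires uniform sampling")
        fs = 1.0 / float(np.median(dts))
    else:
        values = np.asarray(track, dtype=float)
        if fs is None:
            raise ValueError("fs required for array input")
    if values.ndim == 1:
        values = values[:, None]
    if mode == "x":
        values = values[:, :1]
    elif mode == "y":
        values = values[:, 1:2]
    elif mode != "radial":
        raise ValueError("mode must be 'radial', 'x' or 'y'")
    nperseg = values.shape[0] if nperseg is None else nperseg
    total = None
    for c in range(values.shape[1]):
        f, p = signal.welch(
            values[:, c], fs=fs, window=window, nperseg=nperseg, detrend=detrend
        )
        total = p if total is None else total + p
    return f[1:], total[1:]


def average_psd(spectra: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Average spectra estimated on a common frequency grid."""
    f0 = spectra[0][0]
    for f, _ in spectra[1:]:
        if len(f) != len(f0) or not np.allclose(f, f0):
            raise ValueError("spectra must share one frequency grid")
    return f0, np.mean([p for _, p in spectra], axis=0)


def ou_psd(f, b: float, f0: float, teff: float) -> np.ndarray:
    """Analytic one-sided OU spectrum (m²/Hz); ``teff`` in kelvin."""
    f = np.asarray(f, dtype=float)
    return 4.0 * KB * teff / b / ((2 * math.pi) ** 2 * (f**2 + f0**2))


# ---------------------------------------------------------------------------
# Spectral fitting
# ---------------------------------------------------------------------------


@dataclass
class PSDFitResult:
    """Fitted junction-fluctuation spectrum parameters.

    drag b in N s/m, corner frequency f0 in Hz, ``teff_ratio`` = Teff/T.
    ``amplitude`` is the raw fitted level C = 4 kB Teff / b (m²·Hz), the
    quantity a single spectrum actually constrains together with f0.
    """

    b: float
    f0: float
    teff_ratio: float
    amplitude: float
    residual: float
    f_range: tuple[float, float]

    @property
    def stiffness(self) -> float:
        """Trap stiffness k = 2 pi f0 b (N/m)."""
        return 2 * math.pi * self.f0 * self.b


def fit_psd(
    freqs,
    psd,
    T_ambient: float = T_AMBIENT,
    mode: str = "passive",
    b_fixed: float | None = None,
    f0_fixed: float | None = None,
    n_axes: int = 1,
    units: str = "um2",
    f_max: float | None = None,
    bins_per_decade: int = 8,
    downweight_lowest_decade: bool = True,
) -> PSDFitResult:
    """Fit the OU junction spectrum S(f) = 4 kB Teff / b / [(2pi)²(f²+f0²)].

    The fit runs on log S vs log f with equal weight per log-frequency
    bin (the lowest decade down-weighted for window bias), estimating the
    level C = 4 kB Teff/b and the corner f0.  ``mode="passive"`` fixes
    Teff = T_ambient and returns the drag b; ``mode="active"`` requires
    ``b_fixed`` (from the passive fit of the paired control) and returns
    Teff/T.  ``n_axes`` declares how many independent coordinates were
    summed into the input PSD (2 for the default radial spectrum of a 2D
    track, which is fitted as x and y jointly); the model level is
    ``n_axes * C``.  ``f0_fixed`` pins the corner frequency (e.g. to the
    paired passive fit's value: activity raises the noise temperature but
    not the trap mechanics).  ``units="um2"`` declares the input PSD in
    µm²/Hz (track convention); use "m2" for SI input.  ``f_max`` defaults
    to a fifth of the top frequency to avoid the aliased band near
    Nyquist.
    """
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(psd, dtype=float)
    if units == "um2":
        p = p * 1e-12
    elif units != "m2":
        raise ValueError("units must be 'um2' or 'm2'")
    keep = (f > 0) & (p > 0)
    f, p = f[keep], p[keep]
    if f_max is None:
        f_max = f.max() / 5.0
    sel = f <= f_max
    if sel.sum() >= 4:
        f, p = f[sel], p[sel]
    # equal weight per log-frequency bin, applied per point so that a
    # noiseless model spectrum is recovered exactly
    lo, hi = math.log10(f.min()), math.log10(f.max())
    n_bins = max(3, int(math.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, hi, n_bins + 1)
    edges[0] *= 0.999
    edges[-1] *= 1.001
    idx = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    w = np.sqrt(1.0 / counts[idx])
    if downweight_lowest_decade:
        w[f < f.min() * 10] *= 0.5
    fb, pb = f, p
    # initial guesses: level from the f^-2 tail, corner from the plateau
    c0 = np.median(pb * (2 * math.pi) ** 2 * fb**2)
    f0_0 = max(min(math.sqrt(max(c0 / ((2 * math.pi) ** 2 * pb.max()), 1e-30)), fb.max()), fb.min() / 10)

    def resid(theta):
        logc = theta[0]
        logf0 = math.log10(f0_fixed) if f0_fixed is not None else theta[1]
        model = 10.0**logc / ((2 * math.pi) ** 2 * (fb**2 + (10.0**logf0) ** 2))
        return w * (np.log10(model) - np.log10(pb))

    theta0 = [math.log10(c0)] if f0_fixed is not None else [math.log10(c0), math.log10(f0_0)]
    res = optimize.least_squares(resid, theta0, method="lm", max_nfev=10000)
    if not res.success:
        raise FitError(f"spectral fit did not converge: {res.message}; residual={res.cost:.3g}")
    c = 10.0 ** res.x[0] / n_axes
    f0 = f0_fixed if f0_fixed is not None else 10.0 ** res.x[1]
    if mode == "passive":
        teff_ratio = 1.0
        b = 4.0 * KB * T_ambient / c
    elif mode == "active":
        if b_fixed is None:
            raise ValueError("active fit requires b_fixed from the paired passive fit")
        b = b_fixed
        teff_ratio = c * b / (4.0 * KB * T_ambient)
    else:
        raise ValueError("mode must be 'passive' or 'active'")
    residual = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return PSDFitResult(b, f0, teff_ratio, c, residual, (float(fb.min()), float(fb.max())))


# ---------------------------------------------------------------------------
# Effective tension and shape dependence
# ---------------------------------------------------------------------------


@dataclass
class EffectiveTension:
    """Effective tension gamma_e = kB T / sigma from edge-length variance."""

    gamma_e: float
    variance_m2: float
    temperature: float


def effective_tension(variance_m2: float, temperature: float = T_AMBIENT) -> EffectiveTension:
    """Effective edge tension (N/m) from the passive edge-length variance (m²)."""
    if variance_m2 <= 0:
        raise ValueError("variance must be positive")
    return EffectiveTension(KB * temperature / variance_m2, variance_m2, temperature)


def fluctuation_vs_shape(experiments) -> pd.DataFrame:
    """Table pairing per-experiment shape index with pooled edge-fluctuation SD.

    ``experiments`` is an iterable of (shape_index, edge_sd, condition)
    triples or dicts with those keys; one row per experiment.
    """
    rows = []
    for exp in experiments:
        if isinstance(exp, dict):
            rows.append((exp["shape_index"], exp["edge_sd"], exp["condition"]))
        else:
            rows.append(tuple(exp))
    if len(rows) < 2:
        raise ValueError("need at least two experiments")
    return pd.DataFrame(rows, columns=["s", "edge_sd", "condition"])
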