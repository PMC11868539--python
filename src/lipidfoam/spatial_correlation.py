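"""Spatial structure of junction fluctuations.

Cooperative tension generation couples the motion of nearby junctions:
shared forcing by swimmers of one compartment correlates its vertices,
and tension propagation through the elastic network can extend the
correlation further.  This module measures the zero-lag cross
correlation of junction displacement versus pair distance, extracts a
correlation length from the resulting curve, and builds time-resolved
"hotspot" maps of the largest displacement per 60-s window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluctuation_stats import block_series
from .image_analysis import VertexTrack


@dataclass
class CorrelationCurve:
    """Mean zero-lag displacement correlation binned by pair distance.

    ``null_level`` is the 95% significance level of the absolute
    correlation under a circular-shift permutation null (NaN if the null
    was not estimated); ``nn_distance_um`` the mean nearest-neighbour
    junction distance, the natural reference scale of the curve.
    """

    bin_centers_um: np.ndarray
    mean_corr: np.ndarray
    counts: np.ndarray
    null_level: float = float("nan")
    nn_distance_um: float = float("nan")
    pairs: pd.DataFrame | None = field(default=None, repr=False)


def displacement_cross_correlation(
    tracks: list[VertexTrack],
    bin_width_um: float = 10.0,
    block_s: float = 60.0,
    min_common_frames: int = 30,
    n_null_shifts: int = 200,
    seed: int = 0,
    mode: str = "radial",
) -> CorrelationCurve:
    """Zero-lag Pearson correlation of junction displacement vs distance.

    Displacement series are re-centred per 60-s block; the default
    "radial" mode correlates displacement magnitudes (``mode="x"``/"y"
    correlate one vector component).  Every pair with at least
    ``min_common_frames`` common frames contributes one correlation at
    the pair's mean separation; pairs are then binned by distance.  With
    ``n_null_shifts > 0`` a circular-shift permutation null yields the
    95% significance level stored on the curve.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    series, centers = [], []
    for tr in tracks:
        blocked = block_series(tr, block_s)
        if mode == "radial":
            s = np.linalg.norm(blocked.data, axis=2).ravel()
        elif mode in ("x", "y"):
            s = blocked.data[:, :, 0 if mode == "x" else 1].ravel()
        else:
            raise ValueError("mode must be 'radial', 'x' or 'y'")
        series.append(s)
        centers.append(tr.positions.mean(axis=0))
    centers = np.array(centers)
    rng = np.random.default_rng(seed)
    rows, null_vals = [], []
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            n = min(len(series[i]), len(series[j]))
            if n < min_common_frames:
                continue
            a, b = series[i][:n], series[j][:n]
            if a.std() == 0 or b.std() == 0:
                continue
            c = float(np.corrcoef(a, b)[0, 1])
            d = float(np.linalg.norm(centers[i] - centers[j]))
            rows.append((tracks[i].vertex_id, tracks[j].vertex_id, d, c, n))
            if n_null_shifts > 0:
                shifts = rng.integers(1, n, size=n_null_shifts)
                for s in shifts:
                    null_vals.append(abs(float(np.corrcoef(a, np.roll(b, s))[0, 1])))
    if not rows:
        raise ValueError("no track pair has enough common frames")
    pairs = pd.DataFrame(rows, columns=["id_a", "id_b", "distance_um", "pearson", "n_frames"])
    max_d = pairs.distance_um.max()
    n_bins = max(1, int(math.ceil(max_d / bin_width_um)))
    edges = np.arange(n_bins + 1) * bin_width_um
    idx = np.clip(np.digitize(pairs.distance_um, edges) - 1, 0, n_bins - 1)
    bc, mc, counts = [], [], []
    for k in range(n_bins):
        m = idx == k
        if not m.any():
            continue
        bc.append(0.5 * (edges[k] + edges[k + 1]))
        mc.append(float(pairs["pearson"][m].mean()))
        counts.append(int(m.sum()))
    # nearest-neighbour reference distance
    nn = []
    for i in range(len(centers)):
        d = np.linalg.norm(centers - centers[i], axis=1)
        d[i] = np.inf
        nn.append(d.min())
    null_level = float(np.quantile(null_vals, 0.95)) if null_vals else float("nan")
    return CorrelationCurve(
        np.array(bc), np.array(mc), np.array(counts), null_level, float(np.mean(nn)), pairs
    )


@dataclass
class CorrelationLength:
    """Correlation length with a qualifier flag.

    flag is "ok" (threshold crossing found), "no correlation" (already
    insignificant in the first bin) or "censored" (still significant at
    the largest measured distance).
    """

    lcorr_um: float
    flag: str


def correlation_length(
    curve: CorrelationCurve,
    threshold: float | None = 0.05,
    baseline: float | None = None,
) -> CorrelationLength:
    """Distance at which the correlation decays to insignificance.

    The large-distance baseline (default: mean over the outer quartile of
    bins) is subtracted; the correlation length is the first distance at
    which the excess falls below ``threshold`` (default 0.05; pass None
    to use the curve's permutation null level), linearly interpolated
    between bins.
    """
    if len(curve.bin_centers_um) < 3:
        raise ValueError("need at least 3 distance bins")
    c = np.asarray(curve.mean_corr, dtype=float)
    d = np.asarray(curve.bin_centers_um, dtype=float)
    if baseline is None:
        k = max(1, len(c) // 4)
        baseline = float(c[-k:].mean())
    if threshold is None:
        if math.isnan(curve.null_level):
            raise ValueError("no permutation null on curve; pass an explicit threshold")
        threshold = curve.null_level
    excess = c - baseline
    below = excess < threshold
    if below[0]:
        return CorrelationLength(0.0, "no correlation")
    if not below.any():
        return CorrelationLength(float(d[-1]), "censored")
    k = int(np.argmax(below))
    # linear interpolation of the crossing between bins k-1 and k
    x0, x1 = d[k - 1], d[k]
    y0, y1 = excess[k - 1], excess[k]
    lcorr = x0 + (y0 - threshold) * (x1 - x0) / (y0 - y1)
    return CorrelationLength(float(lcorr), "ok")


def hotspot_map(tracks: list[VertexTrack], window_s: float = 60.0) -> pd.DataFrame:
    """Largest displacement of each junction in each 60-s window.

    Returns a long-format table (vertex_id, window, t_start_s, x_um,
    y_um, max_disp_um) where the displacement is measured from the
    window's mean position and (x, y) is that mean.
    """
    rows = []
    for tr in tracks:
        dt = tr.frame_interval
        per = max(1, int(round(window_s / dt)))
        n_windows = max(1, len(tr) // per)
        for w in range(n_windows):
            sl = slice(w * per, (w + 1) * per if (w + 1) * per <= len(tr) else len(tr))
            p = tr.positions[sl]
            center = p.mean(axis=0)
            disp = np.linalg.norm(p - center, axis=1).max()
            rows.append(
                (tr.vertex_id, w, float(tr.times[sl][0]), center[0], center[1], float(disp))
            )
    return pd.DataFrame(
        rows, columns=["vertex_id", "window", "t_start_s", "x_um", "y_um", "max_disp_um"]
    )
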