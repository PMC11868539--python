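"""Vertex tracking and bacterial occupancy from two-channel timelapses.

Mirrors the experimental processing chain: junctions are localised as
local maxima of the smoothed membrane-dye channel, tracked per frame as
the brightest pixel in a region of interest (frames whose maximum drops
more than a tolerance below the running maximum are flagged invalid),
and bacterial occupancy per compartment is the fraction of foreground
pixels of the binarised bacteria channel inside the compartment polygon.

Pixel/µm conventions: image row r maps to y = r * pixel_size, column c
to x = c * pixel_size; conversions round-trip exactly.  Intensities are
treated on an 8-bit (0-255) scale, on which the default tracking
threshold tolerance of 50 is defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu


class TrackingError(RuntimeError):
    """Raised when a track cannot be extracted (e.g. fully dark ROI)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class VertexTrack:
    """Time series of one junction position.

    positions are (n, 2) arrays of (x, y) in µm on the foam coordinate
    convention; ``valid`` flags frames that passed the intensity
    tolerance.  ``roi`` is the pixel rectangle (row0, col0, row1, col1)
    the track was extracted from, when applicable.
    """

    vertex_id: int
    times: np.ndarray
    positions: np.ndarray
    valid: np.ndarray = None
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.times)))

    def mean_position(self) -> np.ndarray:
        return self.positions[self.valid].mean(axis=0)


def tracks_to_frame(tracks: list[VertexTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i, t in enumerate(tr.times):
            rows.append(
                (tr.vertex_id, i, t, tr.positions[i, 0], tr.positions[i, 1], bool(tr.valid[i]))
            )
    return pd.DataFrame(rows, columns=["vertex_id", "frame", "t_s", "x_um", "y_um", "valid"])


def tracks_from_frame(df: pd.DataFrame) -> list[VertexTrack]:
    out = []
    for vid, g in df.groupby("vertex_id"):
        g = g.sort_values("t_s")
        out.append(
            VertexTrack(
                int(vid),
                g.t_s.to_numpy(),
                g[["x_um", "y_um"]].to_numpy(),
                g.valid.to_numpy(dtype=bool),
            )
        )
    return out


@dataclass
class ImageStack:
    """A timelapse: (frames, height, width, channels) with acquisition metadata."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channels: list[str] = field(default_factory=lambda: ["membrane", "bacteria"])

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if np.nanmin(self.data) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., self.channels.index(name)]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    # -- pixel <-> µm -------------------------------------------------------

    def px_to_um(self, rowcol) -> np.ndarray:
        rc = np.asarray(rowcol, dtype=float)
        return np.stack([rc[..., 1], rc[..., 0]], axis=-1) * self.pixel_size_um

    def um_to_px(self, xy) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return np.stack([xy[..., 1], xy[..., 0]], axis=-1) / self.pixel_size_um

    # -- I/O ----------------------------------------------------------------

    def to_tiff(self, path) -> None:
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "channels": self.channels,
            "shape_tchw": list(np.moveaxis(self.data, -1, 1).shape),
        }
        tifffile.imwrite(
            path,
            np.moveaxis(self.data, -1, 1),  # (T, C, H, W)
            description=json.dumps(meta),
            metadata=None,
        )

    @classmethod
    def from_tiff(cls, path) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc)
        data = data.reshape(meta["shape_tchw"])
        data = np.moveaxis(data, 1, -1)
        return cls(
            data,
            pixel_size_um=meta["pixel_size_um"],
            frame_interval_s=meta["frame_interval_s"],
            channels=list(meta["channels"]),
        )


# ---------------------------------------------------------------------------
# Vertex detection and tracking
# ---------------------------------------------------------------------------


def detect_vertices(
    frame: np.ndarray,
    pixel_size_um: float,
    min_separation_um: float,
    smooth_sigma_px: float = 1.0,
    threshold_rel: float = 0.5,
) -> np.ndarray:
    """Candidate junction positions ((x, y) µm) in one membrane frame.

    Junctions are the brightest structures of the membrane channel (three
    films overlap there), so candidates are local maxima of the smoothed
    frame above a threshold relative to the frame maximum, suppressed to a
    minimum mutual separation.  The relative threshold makes detection
    invariant to global intensity scaling.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a single-channel 2D frame")
    if frame.size == 0 or np.ptp(frame) == 0:
        return np.empty((0, 2))
    sm = ndimage.gaussian_filter(frame, smooth_sigma_px)
    min_dist = max(1, int(round(min_separation_um / pixel_size_um)))
    peaks = peak_local_max(
        sm, min_distance=min_dist, threshold_rel=threshold_rel, exclude_border=False
    )
    return np.stack([peaks[:, 1], peaks[:, 0]], axis=-1) * pixel_size_um if len(peaks) else np.empty((0, 2))


def track_vertex(
    stack: ImageStack,
    roi: tuple[int, int, int, int],
    threshold_tolerance: float = 50.0,
    smooth_sigma_px: float = 1.0,
    subpixel: bool = False,
    channel: str = "membrane",
    vertex_id: int = 0,
) -> VertexTrack:
    """Track one junction as the brightest pixel of a smoothed ROI per frame.

    Frames whose ROI maximum falls more than ``threshold_tolerance``
    intensity units (8-bit scale) below the brightest maximum seen across
    the whole track are flagged invalid.  ``subpixel=True`` refines the
    integer argmax by the intensity centroid of its 3x3 neighbourhood;
    raw argmax is the compatibility default.
    """
    r0, c0, r1, c1 = roi
    frames = stack.channel(channel)
    if not (0 <= r0 < r1 <= frames.shape[1] and 0 <= c0 < c1 <= frames.shape[2]):
        raise ValueError("ROI outside frame bounds")
    sub = frames[:, r0:r1, c0:c1].astype(float)
    maxima = np.empty(stack.n_frames)
    pos_px = np.empty((stack.n_frames, 2))
    for i in range(stack.n_frames):
        sm = ndimage.gaussian_filter(sub[i], smooth_sigma_px)
        idx = np.unravel_index(int(np.argmax(sm)), sm.shape)
        maxima[i] = sm[idx]
        rr, cc = float(idx[0]), float(idx[1])
        if subpixel:
            r_lo, r_hi = max(0, idx[0] - 1), min(sm.shape[0], idx[0] + 2)
            c_lo, c_hi = max(0, idx[1] - 1), min(sm.shape[1], idx[1] + 2)
            patch = sm[r_lo:r_hi, c_lo:c_hi]
            w = patch - patch.min()
            if w.sum() > 0:
                gr, gc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
                rr = float((gr * w).sum() / w.sum())
                cc = float((gc * w).sum() / w.sum())
        pos_px[i] = (rr + r0, cc + c0)
    if maxima.max() <= 0:
        raise TrackingError("ROI is fully dark in all frames")
    valid = maxima >= maxima.max() - threshold_tolerance
    positions = np.stack([pos_px[:, 1], pos_px[:, 0]], axis=-1) * stack.pixel_size_um
    return VertexTrack(vertex_id, stack.times(), positions, valid, roi)


def roi_around(stack: ImageStack, xy_um, half_width_um: float) -> tuple[int, int, int, int]:
    """Pixel ROI centred on a µm position, clipped to the frame."""
    r, c = np.asarray(xy_um, float)[::-1] / stack.pixel_size_um
    h = int(round(half_width_um / stack.pixel_size_um))
    H, W = stack.data.shape[1:3]
    return (
        int(max(0, round(r) - h)),
        int(max(0, round(c) - h)),
        int(min(H, round(r) + h + 1)),
        int(min(W, round(c) + h + 1)),
    )


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------


def estimate_occupancy(
    frame: np.ndarray,
    polygons,
    pixel_size_um: float,
    method: str = "otsu",
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-compartment occupancy from a binarised bacteria frame.

    For each compartment polygon (µm coordinates), Phi = foreground pixels
    inside the polygon / total pixels inside.  ``method`` is "otsu" (per
    frame) or "fixed" with an explicit ``threshold``.  Compartments with
    zero interior pixels get NaN and are flagged.

    Returns (phi, flagged) arrays.
    """
    frame = np.asarray(frame, dtype=float)
    if method == "otsu":
        thr = threshold_otsu(frame) if np.ptp(frame) > 0 else np.inf
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarisation needs a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown binarisation method {method!r}")
    fg = frame > thr
    phi = np.empty(len(polygons))
    flagged = np.zeros(len(polygons), dtype=bool)
    for i, poly in enumerate(polygons):
        coords = np.asarray(getattr(poly, "exterior", poly).coords if hasattr(poly, "exterior") else poly)
        rows = coords[:, 1] / pixel_size_um
        cols = coords[:, 0] / pixel_size_um
        rr, cc = draw_polygon(rows, cols, shape=frame.shape)
        if rr.size == 0:
            phi[i] = np.nan
            flagged[i] = True
            continue
        phi[i] = float(fg[rr, cc].mean())
    return phi, flagged


def occupancy_series(
    stack: ImageStack, polygons, method: str = "otsu", threshold: float | None = None
) -> pd.DataFrame:
    """Long-format per-frame occupancy table (compartment_id, frame, phi)."""
    rows = []
    bact = stack.channel("bacteria")
    for f in range(stack.n_frames):
        phi, _ = estimate_occupancy(bact[f], polygons, stack.pixel_size_um, method, threshold)
        for i, p in enumerate(phi):
            rows.append((i, f, p))
    return pd.DataFrame(rows, columns=["compartment_id", "frame", "phi"])


# ---------------------------------------------------------------------------
# Track QC and speed estimation
# ---------------------------------------------------------------------------


def qc_tracks(
    tracks: list[VertexTrack],
    max_jump_um: float,
    max_invalid_fraction: float = 0.2,
) -> tuple[list[VertexTrack], pd.DataFrame]:
    """Drop tracks with signs of defective tracking.

    A track is removed if any displacement between consecutive valid
    frames exceeds ``max_jump_um`` (tracking jumped to another structure)
    or if more than ``max_invalid_fraction`` of its frames are invalid.
    Returns the kept tracks and a rejection report.
    """
    kept, rows = [], []
    for tr in tracks:
        reason = None
        if 1 - tr.valid.mean() > max_invalid_fraction:
            reason = "invalid_frames"
        else:
            p = tr.positions[tr.valid]
            if len(p) > 1 and np.linalg.norm(np.diff(p, axis=0), axis=1).max() > max_jump_um:
                reason = "jump"
        if reason:
            rows.append((tr.vertex_id, reason))
        else:
            kept.append(tr)
    return kept, pd.DataFrame(rows, columns=["vertex_id", "reason"])


def estimate_speed(
    positions: np.ndarray,
    frame_interval_s: float,
    persistence_time_s: float | None = None,
) -> float:
    """Swimmer speed (µm/s) from frame-to-frame displacements.

    The naive estimate mean(|dr|)/dt underestimates the true speed when
    the frame interval is comparable to the orientational persistence
    time.  If ``persistence_time_s`` is given, the closed-form
    active-Brownian mean-square displacement
    ``MSD(t) = 2 v^2 tau^2 (t/tau + exp(-t/tau) - 1)`` is inverted at the
    frame interval instead, which removes that bias.
    """
    p = np.asarray(positions, dtype=float)
    dr2 = np.sum(np.diff(p, axis=0) ** 2, axis=1)
    if persistence_time_s is None:
        return float(np.mean(np.sqrt(dr2)) / frame_interval_s)
    t, tau = frame_interval_s, persistence_time_s
    geom = 2.0 * tau**2 * (t / tau + np.exp(-t / tau) - 1.0)
    return float(np.sqrt(np.mean(dr2) / geom))
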