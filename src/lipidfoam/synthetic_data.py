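"""Ground-truth generators for the foam-analysis pipeline.

Every analysis stage in this package can be exercised on synthetic data
whose generating parameters are known: overdamped (Ornstein-Uhlenbeck)
junction fluctuations in a harmonic potential, whole-network Langevin
dynamics with per-compartment active forcing, confined active Brownian
swimmers with specular wall collisions, Poisson occupancy sampling, and
rendering of two-channel (membrane dye + bacteria) micrograph stacks.

Default parameters reflect the experimental conditions the generators
emulate: 20-50 µm compartments, vertex drag b = 0.5 µN s/m, corner
frequency f0 = 0.9e-3 Hz, active-to-thermal temperature ratio 6.5,
swimmer speed 3.5 µm/s with ~1 s persistence, 0-40 swimmers per
compartment, and imaging at 1 frame/s for 10 min.

All generators are exactly reproducible given (config, seed).
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage, signal
from shapely.geometry import Polygon

from .foam_geometry import (
    KB,
    T_AMBIENT,
    FoamNetwork,
    _edge_key,
    build_hexagonal_lattice,
    tension_hessian,
)
from .image_analysis import ImageStack, VertexTrack, tracks_from_frame, tracks_to_frame


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


class SimulationConfig(BaseModel):
    """Parameters of the overdamped junction-fluctuation simulator.

    The junction obeys ``b dx/dt = -k x + sqrt(2 kB Teff b) xi(t)`` with
    stiffness ``k = 2 pi f0 b``; ``teff_ratio`` is Teff/T (1 for a
    thermal, heat-killed control; ~6.5 with dense live swimmers).
    """

    dt: float = Field(1.0, gt=0, description="integration step (s)")
    duration: float = Field(600.0, gt=0, description="total simulated time (s)")
    sampling_interval: float = Field(1.0, gt=0, description="output sampling (s)")
    temperature: float = Field(T_AMBIENT, gt=0, description="ambient T (K)")
    drag: float = Field(0.5e-6, gt=0, description="drag b (N s/m)")
    f0: float = Field(0.9e-3, gt=0, description="corner frequency (Hz)")
    teff_ratio: float = Field(1.0, gt=0, description="Teff / T")
    seed: int = 0

    @model_validator(mode="after")
    def _check_stability(self):
        if self.dt >= 1.0 / (2 * math.pi * self.f0) / 10.0:
            raise ValueError(
                f"dt={self.dt} too large for f0={self.f0}: need dt < 1/(2 pi f0)/10 "
                f"= {1.0 / (2 * math.pi * self.f0) / 10.0:.3g} s"
            )
        if self.sampling_interval < self.dt:
            raise ValueError("sampling interval must be >= dt")
        return self

    @property
    def stiffness(self) -> float:
        """k = 2 pi f0 b (N/m)."""
        return 2 * math.pi * self.f0 * self.drag


# ---------------------------------------------------------------------------
# OU vertex dynamics
# ---------------------------------------------------------------------------


def simulate_ou_vertex(
    cfg: SimulationConfig, n_dim: int = 2, x0_um=None, vertex_id: int = 0
) -> VertexTrack:
    """Euler-Maruyama integration of an overdamped junction in a harmonic trap.

    Returns a :class:`VertexTrack` in µm sampled at the configured
    interval.  Stationary variance per axis is kB Teff / k and the
    position autocorrelation decays as exp(-2 pi f0 t).
    """
    rng = np.random.default_rng(cfg.seed)
    k, b = cfg.stiffness, cfg.drag
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    stride = int(round(cfg.sampling_interval / dt))
    a = 1.0 - k * dt / b
    sig = math.sqrt(2 * KB * cfg.teff_ratio * cfg.temperature * dt / b)
    x0 = np.zeros(n_dim) if x0_um is None else np.asarray(x0_um, float) * 1e-6
    noise = rng.normal(0.0, sig, size=(n_steps, n_dim))
    # AR(1) recursion x_{n+1} = a x_n + noise_n, run as an IIR filter
    x = signal.lfilter([1.0], [1.0, -a], noise, axis=0, zi=np.outer([a], x0))[0]
    x = np.vstack([x0, x])[::stride]
    times = np.arange(len(x)) * stride * dt
    pos = np.zeros((len(x), 2))
    pos[:, :n_dim] = x * 1e6
    return VertexTrack(vertex_id, times, pos)


# ---------------------------------------------------------------------------
# Whole-network Langevin dynamics with per-compartment active forcing
# ---------------------------------------------------------------------------


@dataclass
class NetworkTrajectory:
    """Trajectory of all junction positions of a foam network.

    positions has shape (n_frames, n_vertices, 2) in µm; ``reference``
    holds the force-balanced rest positions the displacements are
    measured from.
    """

    times: np.ndarray
    vertex_ids: list[int]
    positions: np.ndarray
    reference: np.ndarray
    net: FoamNetwork
    free: np.ndarray

    def track(self, vertex_id: int) -> VertexTrack:
        i = self.vertex_ids.index(vertex_id)
        return VertexTrack(vertex_id, self.times, self.positions[:, i, :])

    def tracks(self, interior_only: bool = True) -> list[VertexTrack]:
        out = []
        for i, vid in enumerate(self.vertex_ids):
            if interior_only and not self.free[i]:
                continue
            out.append(VertexTrack(vid, self.times, self.positions[:, i, :]))
        return out

    def edge_length_series(self, edge) -> np.ndarray:
        a, b = edge
        ia, ib = self.vertex_ids.index(a), self.vertex_ids.index(b)
        return np.linalg.norm(self.positions[:, ia, :] - self.positions[:, ib, :], axis=1)


def _local_stiffness(net: FoamNetwork, tensions: dict, vertex: int) -> float:
    """Mean transverse stiffness (N/m) of a junction with neighbours fixed.

    Half-trace of the Hessian of sum_e T_e L_e at the vertex: each edge
    contributes (T/L)(I - u u^T), i.e. T/(2L) on average per direction.
    """
    x = net.vertices[vertex]
    h = np.zeros((2, 2))
    for nb in net.neighbors(vertex):
        u = net.vertices[nb] - x
        L = np.linalg.norm(u) * 1e-6  # µm -> m
        uhat = u / np.linalg.norm(u)
        h += tensions[_edge_key(vertex, nb)] / L * (np.eye(2) - np.outer(uhat, uhat))
    return float(np.trace(h) / 2.0)


def simulate_network_dynamics(
    net: FoamNetwork,
    edge_tensions: dict,
    cfg: SimulationConfig,
    occupancy=None,
    displacement_per_phi_um: float = 16.4,
    active_tau_s: float = 1.0,
    active_fluctuation: float = 1.0,
    area_stiffness: float | None = None,
    seed: int | None = None,
) -> NetworkTrajectory:
    """Overdamped Langevin dynamics of the whole junction network.

    Each interior junction feels (i) the line-tension and area-elastic
    restoring forces (edge tensions in N), (ii) thermal noise at the
    configured temperature, and (iii) an active swim-pressure force from
    every occupied compartment.  Compartment c's mean force pattern is
    constructed so that its static response displaces c's junctions away
    from the compartment centroid by ``displacement_per_phi_um * Phi_c``
    (see the in-line note on the construction), and the whole pattern is
    modulated by one shared OU factor per compartment (correlation time
    ``active_tau_s``, relative sd ``active_fluctuation``).  Thus the
    time-averaged junction displacements reproduce the linear
    displacement-occupancy law under arbitrary simultaneous loading,
    equally loaded compartments cancel at their shared junction, and
    junctions of one compartment share a force history, which induces
    spatial correlations.

    Line tension alone leaves a foam network floppy; the aqueous
    compartments are effectively incompressible on these timescales, so
    an area-elasticity energy (K_A/2)(A_c - A_c0)^2 per compartment
    rigidifies the network.  ``area_stiffness`` (N/m^3) defaults to
    4 * mean(T_e) / L^3, which makes the area modes comparably stiff to
    the tension modes.

    ``occupancy`` is a per-compartment array of area fractions Phi
    (None = all zero, purely thermal).  Boundary junctions stay pinned.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    vids = sorted(net.vertices)
    index = {v: i for i, v in enumerate(vids)}
    x0 = np.array([net.vertices[v] for v in vids]) * 1e-6  # m
    free = np.array([v not in net.boundary for v in vids])
    edges = np.array([[index[a], index[b]] for a, b in sorted(net.edges)])
    tension = np.array([edge_tensions[e] for e in sorted(net.edges)])

    mean_len_m = float(np.mean([net.edge_length(e) for e in net.edges])) * 1e-6
    if area_stiffness is None:
        area_stiffness = 4.0 * float(np.mean(tension)) / mean_len_m**3

    # compartment cycles flattened for vectorised area forces
    cyc_v, cyc_next, cyc_prev, cyc_comp = [], [], [], []
    for ci, cyc in enumerate(net.compartments):
        n = len(cyc)
        for k, v in enumerate(cyc):
            cyc_v.append(index[v])
            cyc_next.append(index[cyc[(k + 1) % n]])
            cyc_prev.append(index[cyc[k - 1]])
            cyc_comp.append(ci)
    cyc_v, cyc_next, cyc_prev, cyc_comp = map(np.array, (cyc_v, cyc_next, cyc_prev, cyc_comp))
    n_comp = len(net.compartments)

    def signed_areas(pos):
        cross = pos[cyc_v, 0] * pos[cyc_next, 1] - pos[cyc_next, 0] * pos[cyc_v, 1]
        return 0.5 * np.bincount(cyc_comp, cross, minlength=n_comp)

    area0 = signed_areas(x0)

    kv = np.array(
        [_local_stiffness(net, edge_tensions, v) if free[i] else 0.0 for i, v in enumerate(vids)]
    )
    kmax = kv.max() if kv.max() > 0 else 1.0
    kmax = kmax + area_stiffness * mean_len_m**2
    dt = min(cfg.dt, 0.1 * cfg.drag / kmax)
    stride = max(1, int(round(cfg.sampling_interval / dt)))
    dt = cfg.sampling_interval / stride
    n_steps = int(round(cfg.duration / dt))
    b = cfg.drag

    def conservative_force(pos):
        f = np.zeros_like(pos)
        d = pos[edges[:, 1]] - pos[edges[:, 0]]
        L = np.linalg.norm(d, axis=1, keepdims=True)
        fe = tension[:, None] * d / L
        np.add.at(f, edges[:, 0], fe)
        np.add.at(f, edges[:, 1], -fe)
        if area_stiffness > 0:
            d_area = area_stiffness * (signed_areas(pos) - area0)
            grad = 0.5 * np.stack(
                [pos[cyc_next, 1] - pos[cyc_prev, 1], pos[cyc_prev, 0] - pos[cyc_next, 0]],
                axis=-1,
            )
            np.add.at(f, cyc_v, -d_area[cyc_comp, None] * grad)
        return f

    # Active forcing.  Each loaded compartment pushes its junctions away
    # from its centroid by the displacement-law target
    # u_c(v) = displacement_per_phi_um * Phi_c * outward(v).  Because the
    # elastic response of the network is long-ranged, a naive outward
    # force of fixed magnitude would not realise the law once many
    # compartments are loaded; instead the mean force pattern is taken as
    # F_c = H u_c (H the network stiffness), whose static response is the
    # target displacement field exactly, by construction and for any
    # superposition of loaded compartments.  Each compartment's force
    # pattern carries one shared OU factor (correlation time
    # ``active_tau_s``, sd ``active_fluctuation``, clipped at zero since
    # swim pressure cannot pull, with the clipping gain divided out), so
    # junctions of the same compartment stay spatially correlated.
    # Targets are capped at 4% of the compartment diameter: beyond a few
    # percent the inflation mode softens and eventually buckles, and the
    # linear calibration would no longer hold.
    occupancy = np.zeros(len(net.compartments)) if occupancy is None else np.asarray(occupancy, float)
    comp_members: list[tuple[int, np.ndarray, np.ndarray]] = []
    if np.any(occupancy > 0):
        H, free_ids = tension_hessian(net, edge_tensions, area_stiffness=area_stiffness)
        free_index = {v: i for i, v in enumerate(free_ids)}
        r = active_fluctuation
        clip_gain = 1.0
        if r > 0:
            from scipy.stats import norm as _norm

            clip_gain = float(_norm.cdf(1.0 / r) + r * _norm.pdf(1.0 / r))
        for ci, phi in enumerate(occupancy):
            if phi <= 0:
                continue
            centroid = net.compartment_centroid(ci)
            diameter = 2.0 * math.sqrt(abs(area0[ci]) / math.pi)
            target = min(displacement_per_phi_um * 1e-6 * phi, 0.04 * diameter)
            if target <= 0:
                continue
            u_c = np.zeros(H.shape[0])
            for v in net.compartments[ci]:
                if v not in free_index:
                    continue
                u = net.vertices[v] - centroid
                n = np.linalg.norm(u)
                if n == 0:
                    continue
                u_c[2 * free_index[v] : 2 * free_index[v] + 2] = target * u / n
            force_field = (H @ u_c).reshape(-1, 2) / clip_gain
            nonzero = np.flatnonzero(np.linalg.norm(force_field, axis=1) > 0)
            if nonzero.size == 0:
                continue
            members = np.array([index[free_ids[i]] for i in nonzero])
            comp_members.append((ci, members, force_field[nonzero]))

    a_ou = math.exp(-dt / active_tau_s)
    s_ou = math.sqrt(1.0 - a_ou**2)
    comp_state = np.ones(len(comp_members))  # normalised force factor, mean 1
    noise_sd = math.sqrt(2 * KB * cfg.temperature * cfg.teff_ratio * dt / b)

    diam = math.sqrt(np.median([net.compartment_polygon(i).area for i in range(len(net.compartments))])) * 1e-6

    x = x0.copy()
    n_out = n_steps // stride + 1
    out = np.empty((n_out, len(vids), 2))
    out[0] = x * 1e6
    rec = 1
    step = 0
    halvings = 0
    while step < n_steps:
        f = conservative_force(x)
        for ci_idx, (ci, members, fvec) in enumerate(comp_members):
            f[members] += comp_state[ci_idx] * fvec
        dx = f * dt / b + rng.normal(0.0, noise_sd, size=x.shape)
        dx[~free] = 0.0
        if np.linalg.norm(dx, axis=1).max() > diam:
            halvings += 1
            if halvings > 20:
                raise SimulationError("network step repeatedly exceeded the compartment size")
            dt /= 2
            stride *= 2
            n_steps *= 2
            step *= 2
            a_ou = math.exp(-dt / active_tau_s)
            s_ou = math.sqrt(1.0 - a_ou**2)
            noise_sd = math.sqrt(2 * KB * cfg.temperature * cfg.teff_ratio * dt / b)
            continue
        x = x + dx
        comp_state = 1.0 + a_ou * (comp_state - 1.0) + active_fluctuation * s_ou * rng.normal(
            size=comp_state.shape
        )
        np.clip(comp_state, 0.0, None, out=comp_state)
        step += 1
        if step % stride == 0:
            out[rec] = x * 1e6
            rec += 1
    times = np.arange(rec) * cfg.sampling_interval
    return NetworkTrajectory(times, vids, out[:rec], x0 * 1e6, net, free)


# ---------------------------------------------------------------------------
# Active Brownian swimmers
# ---------------------------------------------------------------------------


@dataclass
class SwimmerPopulation:
    """Swimmers of one compartment: positions (µm), orientations (rad)."""

    positions: np.ndarray
    orientations: np.ndarray
    speed: float = 3.5
    persistence_time: float = 1.0
    footprint_um2: float = 2.0


@dataclass
class ABPResult:
    times: np.ndarray
    positions: np.ndarray  # (n_frames, n, 2) µm
    orientations: np.ndarray
    collisions: pd.DataFrame


def _reflect_once(p_in, p_out, u, poly_coords):
    """Reflect a wall crossing; returns (position, direction, collision info)."""
    best_t, best = np.inf, None
    n_seg = len(poly_coords)
    for k in range(n_seg):
        s0 = poly_coords[k]
        s1 = poly_coords[(k + 1) % n_seg]
        d = p_out - p_in
        e = s1 - s0
        denom = d[0] * e[1] - d[1] * e[0]
        if abs(denom) < 1e-15:
            continue
        t = ((s0[0] - p_in[0]) * e[1] - (s0[1] - p_in[1]) * e[0]) / denom
        s = ((s0[0] - p_in[0]) * d[1] - (s0[1] - p_in[1]) * d[0]) / denom
        if -1e-9 <= t < best_t and t <= 1 + 1e-9 and -1e-9 <= s <= 1 + 1e-9:
            best_t, best = t, (s0, s1)
    if best is None:
        return None
    s0, s1 = best
    e = (s1 - s0) / np.linalg.norm(s1 - s0)
    n = np.array([-e[1], e[0]])
    q = p_in + best_t * (p_out - p_in)
    p_ref = p_out - 2 * np.dot(p_out - q, n) * n
    u_ref = u - 2 * np.dot(u, n) * n
    incidence = math.degrees(math.acos(min(1.0, abs(float(np.dot(u, n))))))
    return p_ref, u_ref, (q, incidence, 2.0 * abs(float(np.dot(u, n))))


def simulate_abp(
    domain,
    n: int,
    v: float = 3.5,
    tau: float = 1.0,
    dt: float = 0.05,
    duration: float = 60.0,
    seed: int = 0,
    record_every: int = 1,
) -> ABPResult:
    """Active Brownian particles confined to a polygon with specular walls.

    Constant speed ``v`` (µm/s); the heading diffuses with rotational
    diffusivity 1/tau, so the swimming direction decorrelates as
    exp(-t/tau).  Wall contacts are resolved by specular reflection and
    logged with position, incidence angle (degrees from the wall normal)
    and momentum transfer per unit mass (2 v cos(incidence), µm/s).
    Pass ``domain=None`` for unbounded motion.
    """
    if v < 0 or tau <= 0 or dt <= 0 or duration <= 0:
        raise ValueError("speed, persistence time, dt and duration must be positive")
    rng = np.random.default_rng(seed)
    coords = None
    if domain is not None:
        poly = domain if isinstance(domain, Polygon) else Polygon(np.asarray(domain))
        if not poly.is_valid:
            raise ValueError("domain polygon must be simple")
        coords = np.asarray(poly.exterior.coords)[:-1]
        seg_len = np.linalg.norm(np.diff(np.vstack([coords, coords[:1]]), axis=0), axis=1)
        if v * dt > 0.1 * seg_len.min():
            raise SimulationError(
                f"dt={dt} cannot resolve wall crossings: v*dt={v * dt:.3g} µm "
                f"exceeds 10% of the shortest wall segment ({seg_len.min():.3g} µm)"
            )
        path = MplPath(coords)
        # start uniformly inside
        xmin, ymin, xmax, ymax = poly.bounds
        pos = np.empty((n, 2))
        got = 0
        while got < n:
            cand = rng.uniform((xmin, ymin), (xmax, ymax), size=(4 * n, 2))
            inside = path.contains_points(cand)
            take = cand[inside][: n - got]
            pos[got : got + len(take)] = take
            got += len(take)
    else:
        pos = np.zeros((n, 2))
    theta = rng.uniform(0, 2 * math.pi, size=n)
    n_steps = int(round(duration / dt))
    n_rec = n_steps // record_every + 1
    positions = np.empty((n_rec, n, 2))
    orientations = np.empty((n_rec, n))
    positions[0], orientations[0] = pos, theta
    collisions = []
    rot_sd = math.sqrt(2.0 * dt / tau)
    rec = 1
    for step in range(1, n_steps + 1):
        theta = theta + rng.normal(0.0, rot_sd, size=n)
        u = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        new = pos + v * dt * u
        if coords is not None:
            outside = ~MplPath(coords).contains_points(new)
            for i in np.flatnonzero(outside):
                p_in, p_out, ui = pos[i], new[i], u[i]
                for _ in range(8):
                    hit = _reflect_once(p_in, p_out, ui, coords)
                    if hit is None:
                        break
                    p_out, ui, (q, inc, dp) = hit
                    collisions.append((step * dt, i, q[0], q[1], inc, dp * v))
                    if MplPath(coords).contains_point(p_out):
                        break
                    p_in = q
                if not MplPath(coords).contains_point(p_out):
                    p_out = pos[i]  # degenerate corner: stay put this step
                new[i] = p_out
                theta[i] = math.atan2(ui[1], ui[0])
        pos = new
        if step % record_every == 0:
            positions[rec], orientations[rec] = pos, theta
            rec += 1
    times = np.arange(n_rec) * dt * record_every
    coll = pd.DataFrame(
        collisions, columns=["t_s", "particle", "x_um", "y_um", "incidence_deg", "dp_um_s"]
    )
    return ABPResult(times, positions[:rec], orientations[:rec], coll)


# ---------------------------------------------------------------------------
# Occupancy sampling
# ---------------------------------------------------------------------------

MAX_SWIMMERS = 40


def sample_occupancy(
    mean_count: float,
    footprint_um2: float,
    areas_um2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson swimmer counts (truncated at 40) and area-fraction occupancies.

    Returns (phi, counts); phi_n = count * footprint / area, clipped to
    [0, 1].
    """
    if mean_count < 0:
        raise ValueError("mean count must be non-negative")
    rng = np.random.default_rng(seed)
    areas = np.asarray(areas_um2, dtype=float)
    counts = rng.poisson(mean_count, size=areas.shape)
    while np.any(counts > MAX_SWIMMERS):  # truncated distribution: redraw
        high = counts > MAX_SWIMMERS
        counts[high] = rng.poisson(mean_count, size=int(high.sum()))
    phi = np.clip(counts * footprint_um2 / areas, 0.0, 1.0)
    return phi, counts


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

MEMBRANE_PEAK = 80.0  # per-edge line intensity before blur (8-bit scale)
BACTERIA_PEAK = 200.0


def render_micrograph(
    net: FoamNetwork,
    vertex_positions: np.ndarray | None = None,
    vertex_ids: list[int] | None = None,
    swimmers: list[np.ndarray] | None = None,
    pixel_size_um: float = 0.5,
    psf_sigma_um: float = 0.6,
    noise_level: float = 0.0,
    seed: int = 0,
    frame_interval_s: float = 1.0,
    footprint_um2: float = 2.0,
    margin_um: float = 5.0,
) -> tuple[ImageStack, dict]:
    """Render a two-channel micrograph stack from network + swimmer state.

    The membrane channel rasterises every edge as a line and blurs with a
    Gaussian point-spread function; junctions are brightest because three
    edges overlap there.  The bacteria channel rasterises swimmer
    footprints as disks.  With ``noise_level > 0``, Poisson shot noise
    plus Gaussian read noise of that standard deviation are added.

    ``vertex_positions`` is (n_frames, n_vertices, 2) µm (defaults to one
    static frame of the network); ``swimmers`` is a per-frame list of
    (n_swimmers, 2) arrays.  Returns the stack and a ground-truth dict.
    """
    import warnings

    from skimage.draw import disk, line_aa

    if psf_sigma_um > 0 and pixel_size_um >= 4 * psf_sigma_um:
        warnings.warn("pixel size exceeds the PSF support; the stack is undersampled")
    if vertex_ids is None:
        vertex_ids = sorted(net.vertices)
    if vertex_positions is None:
        vertex_positions = np.array([[net.vertices[v] for v in vertex_ids]])
    vertex_positions = np.asarray(vertex_positions, dtype=float)
    n_frames = len(vertex_positions)
    xmin, ymin, xmax, ymax = net.bounding_box()
    if vertex_positions[..., 0].max() > xmax:
        xmax = vertex_positions[..., 0].max()
    if vertex_positions[..., 1].max() > ymax:
        ymax = vertex_positions[..., 1].max()
    W = int(math.ceil((xmax - xmin + 2 * margin_um) / pixel_size_um))
    H = int(math.ceil((ymax - ymin + 2 * margin_um) / pixel_size_um))
    origin = np.array([xmin - margin_um, ymin - margin_um])
    idx = {v: i for i, v in enumerate(vertex_ids)}
    edges = [(idx[a], idx[b]) for a, b in sorted(net.edges) if a in idx and b in idx]
    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma_um / pixel_size_um
    r_disk = max(1.0, math.sqrt(footprint_um2 / math.pi) / pixel_size_um)
    data = np.zeros((n_frames, H, W, 2), dtype=np.float32)  # quantised to uint8 at the end
    for f in range(n_frames):
        mem = np.zeros((H, W), dtype=float)
        pts_px = (vertex_positions[f] - origin) / pixel_size_um
        for ia, ib in edges:
            c0, r0 = pts_px[ia]
            c1, r1 = pts_px[ib]
            rr, cc, val = line_aa(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            mem[rr[keep], cc[keep]] += MEMBRANE_PEAK * val[keep]
        if sigma_px > 0:
            mem = ndimage.gaussian_filter(mem, sigma_px)
        bact = np.zeros((H, W), dtype=float)
        if swimmers is not None and swimmers[f] is not None and len(swimmers[f]):
            for x, y in np.asarray(swimmers[f]):
                rr, cc = disk(((y - origin[1]) / pixel_size_um, (x - origin[0]) / pixel_size_um), r_disk, shape=(H, W))
                bact[rr, cc] = BACTERIA_PEAK
        if noise_level > 0:
            mem = rng.poisson(np.clip(mem, 0, None)).astype(float) + rng.normal(0, noise_level, mem.shape)
            bact = rng.poisson(np.clip(bact, 0, None)).astype(float) + rng.normal(0, noise_level, bact.shape)
        data[f, ..., 0] = np.clip(mem, 0, 255)
        data[f, ..., 1] = np.clip(bact, 0, 255)
    stack = ImageStack(np.round(data).astype(np.uint8), pixel_size_um, frame_interval_s)
    truth = {
        "origin_um": origin,
        "vertex_ids": vertex_ids,
        "vertex_positions_um": vertex_positions - origin,  # in stack coordinates
        "binarisation_threshold": BACTERIA_PEAK / 2.0,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------


class ScenarioConfig(BaseModel):
    """Composite configuration for a full synthetic experiment.

    ``mode`` is "active" (live swimmers: occupancy-dependent junction
    forcing with relative fluctuation ``active_fluctuation``, swimmers
    moving at ``swimmer_speed``) or "heat-killed" (v = 0, thermal
    fluctuations only; identical geometry, rendering and noise).  All
    activity enters through the per-compartment forcing, whose mean is
    calibrated by ``displacement_per_phi_um`` to the linear displacement
    law; the elevated effective temperature of active samples then
    emerges from the forcing rather than being imposed.
    ``teff_ratio_active`` optionally adds extra isotropic bath agitation
    in active mode (default 1 = none).
    """

    n_rows: int = Field(3, ge=1)
    n_cols: int = Field(3, ge=1)
    edge_length_um: float = Field(15.0, gt=0)
    mode: str = "active"
    duration_s: float = Field(600.0, gt=0)
    frame_interval_s: float = Field(1.0, gt=0)
    temperature: float = Field(T_AMBIENT, gt=0)
    drag: float = Field(0.5e-6, gt=0)
    edge_tension: float = Field(1.0e-12, gt=0, description="line tension per edge (N)")
    teff_ratio_active: float = Field(1.0, gt=0)
    mean_count: float = Field(10.0, ge=0)
    footprint_um2: float = Field(2.0, gt=0)
    swimmer_speed: float = Field(3.5, ge=0)
    swimmer_tau: float = Field(1.0, gt=0)
    displacement_per_phi_um: float = Field(16.4, ge=0)
    active_fluctuation: float = Field(1.0, ge=0)
    pixel_size_um: float = Field(0.5, gt=0)
    psf_sigma_um: float = Field(0.6, ge=0)
    noise_level: float = Field(0.0, ge=0)
    render: bool = True
    simulate_swimmers: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check_mode(self):
        if self.mode not in ("active", "heat-killed"):
            raise ValueError("mode must be 'active' or 'heat-killed'")
        return self


@dataclass
class ScenarioBundle:
    """Everything one synthetic experiment produces, with ground truth."""

    config: ScenarioConfig
    net: FoamNetwork
    trajectory: NetworkTrajectory
    occupancy: np.ndarray
    counts: np.ndarray
    swimmer_tracks: list[ABPResult] | None
    stack: ImageStack | None
    truth: dict | None


def generate_scenario(cfg: ScenarioConfig) -> ScenarioBundle:
    """Generate a complete synthetic experiment from one config.

    Builds the honeycomb network, samples per-compartment swimmer counts,
    runs the junction Langevin dynamics (with active forcing in "active"
    mode), simulates confined swimmers, and optionally renders the
    two-channel stack.  Deterministic given the config (which includes
    the seed).
    """
    active = cfg.mode == "active"
    net = build_hexagonal_lattice(cfg.n_rows, cfg.n_cols, cfg.edge_length_um)
    areas = np.array([net.compartment_polygon(i).area for i in range(len(net.compartments))])
    phi, counts = sample_occupancy(cfg.mean_count, cfg.footprint_um2, areas, seed=cfg.seed + 1)
    sim_cfg = SimulationConfig(
        dt=min(0.5, cfg.frame_interval_s),
        duration=cfg.duration_s,
        sampling_interval=cfg.frame_interval_s,
        temperature=cfg.temperature,
        drag=cfg.drag,
        f0=1e-4,  # placeholder; network stiffness sets the actual dynamics
        teff_ratio=cfg.teff_ratio_active if active else 1.0,
        seed=cfg.seed,
    )
    tensions = {e: cfg.edge_tension for e in net.edges}
    traj = simulate_network_dynamics(
        net,
        tensions,
        sim_cfg,
        occupancy=phi if active else None,
        displacement_per_phi_um=cfg.displacement_per_phi_um,
        active_tau_s=cfg.swimmer_tau,
        active_fluctuation=cfg.active_fluctuation,
        seed=cfg.seed + 2,
    )
    swimmer_tracks = None
    swimmer_frames = None
    if cfg.simulate_swimmers:
        swimmer_tracks = []
        n_frames = len(traj.times)
        swimmer_frames = [np.empty((0, 2)) for _ in range(n_frames)]
        speed = cfg.swimmer_speed if active else 0.0
        for ci, cnt in enumerate(counts):
            if cnt == 0:
                continue
            poly = net.compartment_polygon(ci).buffer(-0.5)
            dt_abp = min(0.2, cfg.frame_interval_s)
            if speed > 0:
                seg = min(
                    np.linalg.norm(np.diff(np.asarray(poly.exterior.coords), axis=0), axis=1)
                )
                dt_abp = min(dt_abp, 0.09 * seg / speed)
            res = simulate_abp(
                poly,
                int(cnt),
                v=speed,
                tau=cfg.swimmer_tau,
                dt=dt_abp,
                duration=cfg.duration_s,
                seed=cfg.seed + 10 + ci,
                record_every=max(1, int(round(cfg.frame_interval_s / dt_abp))),
            )
            swimmer_tracks.append(res)
            for f in range(n_frames):
                fi = min(f, len(res.positions) - 1)
                swimmer_frames[f] = np.vstack([swimmer_frames[f], res.positions[fi]])
    stack = truth = None
    if cfg.render:
        stack, truth = render_micrograph(
            net,
            vertex_positions=traj.positions,
            vertex_ids=traj.vertex_ids,
            swimmers=swimmer_frames,
            pixel_size_um=cfg.pixel_size_um,
            psf_sigma_um=cfg.psf_sigma_um,
            noise_level=cfg.noise_level,
            seed=cfg.seed + 3,
            frame_interval_s=cfg.frame_interval_s,
            footprint_um2=cfg.footprint_um2,
        )
        truth["occupancy"] = phi
    return ScenarioBundle(cfg, net, traj, phi, counts, swimmer_tracks, stack, truth)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------


def write_bundle(bundle: ScenarioBundle, outdir) -> None:
    """Write a scenario bundle: TIFF stack, track/occupancy CSVs, network JSON."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(bundle.config.model_dump_json(indent=2))
    (outdir / "network.json").write_text(bundle.net.to_json())
    tracks_to_frame(bundle.trajectory.tracks(interior_only=False)).to_csv(
        outdir / "tracks.csv", index=False
    )
    ref = pd.DataFrame(
        {
            "vertex_id": bundle.trajectory.vertex_ids,
            "x_um": bundle.trajectory.reference[:, 0],
            "y_um": bundle.trajectory.reference[:, 1],
        }
    )
    ref.to_csv(outdir / "reference_positions.csv", index=False)
    pd.DataFrame(
        {
            "compartment_id": range(len(bundle.occupancy)),
            "count": bundle.counts,
            "phi": bundle.occupancy,
        }
    ).to_csv(outdir / "occupancy.csv", index=False)
    if bundle.stack is not None:
        bundle.stack.to_tiff(outdir / "stack.tiff")


def read_bundle(outdir) -> dict:
    """Read a written bundle back (tracks, network, occupancy, stack)."""
    outdir = pathlib.Path(outdir)
    out = {
        "config": ScenarioConfig.model_validate_json((outdir / "config.json").read_text()),
        "net": FoamNetwork.from_json((outdir / "network.json").read_text()),
        "tracks": tracks_from_frame(pd.read_csv(outdir / "tracks.csv")),
        "occupancy": pd.read_csv(outdir / "occupancy.csv"),
        "reference": pd.read_csv(outdir / "reference_positions.csv"),
    }
    if (outdir / "stack.tiff").exists():
        out["stack"] = ImageStack.from_tiff(outdir / "stack.tiff")
    return out
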