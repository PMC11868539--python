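"""Geometry and mechanics of 2D lipid foams.

A lipid-foam prototissue is a planar packing of aqueous compartments
separated by lipid-bilayer films.  The films meet at three-way junctions
("vertices") whose positions reflect the balance of the three film
tensions; an edge is the bilayer segment between two junctions.  This
module provides the network container, builders for reference geometries
(regular honeycomb and jittered-Voronoi disordered foams), per-compartment
shape statistics, the tension relations at a junction and between the
bilayer and its two monolayer leaflets, and the T1 topological
rearrangement that swaps neighbouring compartments.

Conventions
-----------
* Coordinates are continuous 2D Cartesian positions in micrometres,
  y increasing upward.  Pixel conversions live in :mod:`image_analysis`.
* Tensions are in mN/m unless a function documents otherwise; pressures
  in Pa; edge tensions passed to the force-balance helpers are line
  tensions (force units) and only ratios matter there.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

# ---------------------------------------------------------------------------
# Physical constants and reference values
# ---------------------------------------------------------------------------

KB = 1.380649e-23
"""Boltzmann constant (J/K)."""

T_AMBIENT = 298.0
"""Default ambient temperature (K); kB*T = 4.11e-21 J."""

HEX_SHAPE_INDEX = 6.0 / math.sqrt(1.5 * math.sqrt(3.0))
"""Shape index p/sqrt(A) of a regular hexagon (= 3.7224)."""

RIGIDITY_SHAPE_INDEX = 3.81
"""Density-independent rigidity (unjamming) transition of vertex models."""

CONFLUENCE_RATIO = 0.23
"""Minimum bilayer/monolayer tension ratio for a confluent packing."""

RIGIDITY_RATIO = 2.0
"""Tension ratio at the rigidity transition (fully unzipped limit)."""


class FoamGeometryError(ValueError):
    """Invalid argument or geometry for a foam operation."""


class RelaxationError(RuntimeError):
    """Vertex relaxation failed to converge; carries diagnostics."""


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------


def _edge_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class FoamNetwork:
    """Planar network of degree-3 junctions bounding polygonal compartments.

    Attributes
    ----------
    vertices
        Map vertex id -> (x, y) position in µm.
    edges
        Set of unordered vertex-id pairs stored as sorted tuples.
    compartments
        List of compartments, each an ordered cycle of vertex ids.
    boundary
        Ids of boundary vertices (degree < 3 or clipped by the field of
        view).  Boundary compartments are excluded from shape summaries.
    """

    vertices: dict[int, np.ndarray]
    edges: set[tuple[int, int]]
    compartments: list[list[int]]
    boundary: set[int] = field(default_factory=set)

    # -- basic queries ------------------------------------------------------

    def position(self, v: int) -> np.ndarray:
        return self.vertices[v]

    def neighbors(self, v: int) -> list[int]:
        return [b if a == v else a for (a, b) in self.edges if v in (a, b)]

    def degree(self, v: int) -> int:
        return len(self.neighbors(v))

    def edge_length(self, edge: tuple[int, int]) -> float:
        a, b = edge
        return float(np.linalg.norm(self.vertices[a] - self.vertices[b]))

    def compartment_polygon(self, i: int) -> Polygon:
        return Polygon([tuple(self.vertices[v]) for v in self.compartments[i]])

    def compartment_centroid(self, i: int) -> np.ndarray:
        c = self.compartment_polygon(i).centroid
        return np.array([c.x, c.y])

    def interior_vertices(self) -> list[int]:
        return [v for v in self.vertices if v not in self.boundary]

    def interior_compartments(self) -> list[int]:
        return [
            i
            for i, cyc in enumerate(self.compartments)
            if not any(v in self.boundary for v in cyc)
        ]

    def compartments_of_edge(self, edge: tuple[int, int]) -> list[int]:
        a, b = edge
        out = []
        for i, cyc in enumerate(self.compartments):
            n = len(cyc)
            for j in range(n):
                if {cyc[j], cyc[(j + 1) % n]} == {a, b}:
                    out.append(i)
                    break
        return out

    def compartments_of_vertex(self, v: int) -> list[int]:
        return [i for i, cyc in enumerate(self.compartments) if v in cyc]

    def graph(self):
        import networkx as nx

        g = nx.Graph()
        for v, p in self.vertices.items():
            g.add_node(v, pos=tuple(p), boundary=v in self.boundary)
        g.add_edges_from(self.edges)
        return g

    def copy(self) -> "FoamNetwork":
        return FoamNetwork(
            vertices={v: p.copy() for v, p in self.vertices.items()},
            edges=set(self.edges),
            compartments=[list(c) for c in self.compartments],
            boundary=set(self.boundary),
        )

    def bounding_box(self) -> tuple[float, float, float, float]:
        pts = np.array(list(self.vertices.values()))
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise FoamGeometryError on failure."""
        for v, p in self.vertices.items():
            if not np.all(np.isfinite(p)):
                raise FoamGeometryError(f"vertex {v} has non-finite position")
        for e in self.edges:
            if self.edge_length(e) <= 0:
                raise FoamGeometryError(f"edge {e} has non-positive length")
        for v in self.vertices:
            if v not in self.boundary and self.degree(v) != 3:
                raise FoamGeometryError(
                    f"interior vertex {v} has degree {self.degree(v)} != 3"
                )
        for i in range(len(self.compartments)):
            poly = self.compartment_polygon(i)
            if not poly.is_valid:
                raise FoamGeometryError(f"compartment {i} is self-intersecting")
        for e in self.edges:
            if len(self.compartments_of_edge(e)) > 2:
                raise FoamGeometryError(f"edge {e} borders more than 2 compartments")

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "vertices": {str(v): [float(p[0]), float(p[1])] for v, p in self.vertices.items()},
                "edges": sorted(list(e) for e in self.edges),
                "compartments": self.compartments,
                "boundary": sorted(self.boundary),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FoamNetwork":
        d = json.loads(text)
        return cls(
            vertices={int(v): np.asarray(p, dtype=float) for v, p in d["vertices"].items()},
            edges={_edge_key(a, b) for a, b in d["edges"]},
            compartments=[list(c) for c in d["compartments"]],
            boundary=set(d["boundary"]),
        )

    def write(self, prefix) -> None:
        """Write vertex table, edge list and compartment table next to *prefix*."""
        import pathlib

        prefix = pathlib.Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "id": list(self.vertices),
                "x_um": [self.vertices[v][0] for v in self.vertices],
                "y_um": [self.vertices[v][1] for v in self.vertices],
                "boundary": [v in self.boundary for v in self.vertices],
            }
        ).to_csv(f"{prefix}_vertices.csv", index=False)
        with open(f"{prefix}_edges.txt", "w") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a} {b}\n")
        pd.DataFrame(
            {
                "compartment_id": range(len(self.compartments)),
                "vertex_ids": [" ".join(map(str, c)) for c in self.compartments],
            }
        ).to_csv(f"{prefix}_compartments.csv", index=False)

    @classmethod
    def read(cls, prefix) -> "FoamNetwork":
        verts = pd.read_csv(f"{prefix}_vertices.csv")
        vertices = {
            int(r.id): np.array([r.x_um, r.y_um]) for r in verts.itertuples()
        }
        boundary = {int(r.id) for r in verts.itertuples() if r.boundary}
        edges = set()
        with open(f"{prefix}_edges.txt") as fh:
            for line in fh:
                a, b = map(int, line.split())
                edges.add(_edge_key(a, b))
        comps = pd.read_csv(f"{prefix}_compartments.csv")
        compartments = [list(map(int, s.split())) for s in comps.vertex_ids]
        return cls(vertices, edges, compartments, boundary)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_hexagonal_lattice(
    n_rows: int, n_cols: int, edge_length: float
) -> FoamNetwork:
    """Regular honeycomb of ``n_rows x n_cols`` hexagonal compartments.

    Flat-top hexagons of side ``edge_length`` (µm).  All interior vertices
    have degree 3 and every interior compartment is a regular hexagon,
    giving the reference shape index 3.722.
    """
    if n_rows < 1 or n_cols < 1 or edge_length <= 0:
        raise FoamGeometryError("lattice dimensions and edge length must be positive")
    a = float(edge_length)
    tol = a * 1e-6
    corners_angle = np.deg2rad(np.arange(0, 360, 60))
    vid: dict[tuple[int, int], int] = {}
    vertices: dict[int, np.ndarray] = {}
    edges: set[tuple[int, int]] = set()
    compartments: list[list[int]] = []

    def vertex_id(x: float, y: float) -> int:
        key = (int(round(x / tol)), int(round(y / tol)))
        if key not in vid:
            vid[key] = len(vid)
            vertices[vid[key]] = np.array([x, y])
        return vid[key]

    for j in range(n_cols):
        for i in range(n_rows):
            cx = 1.5 * a * j
            cy = math.sqrt(3) * a * i + (math.sqrt(3) * a / 2 if j % 2 else 0.0)
            cyc = [
                vertex_id(cx + a * math.cos(t), cy + a * math.sin(t))
                for t in corners_angle
            ]
            n = len(cyc)
            for k in range(n):
                edges.add(_edge_key(cyc[k], cyc[(k + 1) % n]))
            compartments.append(cyc)

    net = FoamNetwork(vertices, edges, compartments)
    net.boundary = {v for v in vertices if net.degree(v) < 3}
    return net


def _voronoi_cells(points: np.ndarray, bbox: tuple[float, float, float, float]):
    """Voronoi cells of *points* clipped to *bbox* via mirror padding."""
    xmin, ymin, xmax, ymax = bbox
    mirrored = [points]
    for axis, lo, hi in ((0, xmin, xmax), (1, ymin, ymax)):
        for bound in (lo, hi):
            m = points.copy()
            m[:, axis] = 2 * bound - m[:, axis]
            mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    clip = box(xmin, ymin, xmax, ymax)
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise FoamGeometryError("unbounded Voronoi cell despite mirror padding")
        poly = Polygon(vor.vertices[region])
        poly = poly.intersection(clip)
        cells.append(np.asarray(poly.exterior.coords)[:-1])
    return cells


def _network_from_cells(cells, spacing: float) -> FoamNetwork:
    tol = spacing * 1e-6
    vid: dict[tuple[int, int], int] = {}
    vertices: dict[int, np.ndarray] = {}
    edges: set[tuple[int, int]] = set()
    compartments: list[list[int]] = []
    for coords in cells:
        cyc = []
        for x, y in coords:
            key = (int(round(x / tol)), int(round(y / tol)))
            if key not in vid:
                vid[key] = len(vid)
                vertices[vid[key]] = np.array([x, y])
            v = vid[key]
            if not cyc or cyc[-1] != v:
                cyc.append(v)
        if cyc[0] == cyc[-1]:
            cyc = cyc[:-1]
        n = len(cyc)
        for k in range(n):
            edges.add(_edge_key(cyc[k], cyc[(k + 1) % n]))
        compartments.append(cyc)
    return FoamNetwork(vertices, edges, compartments)


def build_disordered_foam(
    n_cells: int,
    disorder: float,
    seed: int,
    spacing: float = 40.0,
) -> FoamNetwork:
    """Disordered foam from a jittered triangular lattice of cell centres.

    Cell centres form a triangular lattice of spacing ``spacing`` (µm,
    the compartment diameter scale) and are displaced by a Gaussian
    jitter of standard deviation ``disorder * spacing``.  The Voronoi
    tessellation of the jittered centres, clipped to the lattice
    bounding box, is the foam.  At ``disorder = 0`` this reduces to the
    regular honeycomb (mean interior shape index 3.722); moderate
    disorder (~0.3) yields the 3.75-3.85 shape-index range typical of
    centrifugation-prepared foams with packing defects.

    The cell count is rounded up to fill a rectangular grid.
    """
    if n_cells < 4:
        raise FoamGeometryError("need at least 4 cells")
    if disorder < 0:
        raise FoamGeometryError("disorder must be non-negative")
    rng = np.random.default_rng(seed)
    nr = int(round(math.sqrt(n_cells)))
    nc = int(math.ceil(n_cells / nr))
    d = float(spacing)
    pts = []
    for r in range(nr):
        for c in range(nc):
            pts.append((c * d + (d / 2 if r % 2 else 0.0), r * d * math.sqrt(3) / 2))
    pts = np.asarray(pts, dtype=float)
    # jitter scale calibrated against the jitter -> shape-index curve so that
    # disorder ~ 0.3 lands in the experimentally observed range s = 3.75-3.85
    sigma = 0.4 * disorder * d
    jitter = rng.normal(0.0, sigma, size=pts.shape) if disorder > 0 else 0.0
    margin = d / 2
    bbox = (
        pts[:, 0].min() - margin,
        pts[:, 1].min() - margin,
        pts[:, 0].max() + margin,
        pts[:, 1].max() + margin,
    )
    points = pts + jitter
    # keep centres inside the clip box so the mirror construction stays valid
    eps = 1e-3 * d
    points[:, 0] = np.clip(points[:, 0], bbox[0] + eps, bbox[2] - eps)
    points[:, 1] = np.clip(points[:, 1], bbox[1] + eps, bbox[3] - eps)
    for attempt in range(5):
        try:
            cells = _voronoi_cells(points, bbox)
            net = _network_from_cells(cells, d)
        except Exception:
            if attempt == 4:
                raise
            points = points + rng.normal(0.0, 1e-9 * d, size=points.shape)
            continue
        xmin, ymin, xmax, ymax = bbox
        eps = 1e-6 * d
        net.boundary = {
            v
            for v, p in net.vertices.items()
            if net.degree(v) < 3
            or p[0] < xmin + eps
            or p[0] > xmax - eps
            or p[1] < ymin + eps
            or p[1] > ymax - eps
        }
        bad = [v for v in net.interior_vertices() if net.degree(v) != 3]
        if not bad:
            return net
        # degenerate (degree != 3) junction: perturb the seeds and retry
        points = points + rng.normal(0.0, 1e-6 * d, size=points.shape)
    raise FoamGeometryError("could not build a degree-3 foam from these seeds")


# ---------------------------------------------------------------------------
# Shape statistics
# ---------------------------------------------------------------------------


def shape_index(polygon) -> float:
    """Shape index s = perimeter / sqrt(area) of a simple polygon.

    3.7224 for a regular hexagon, 4 for a square, with the isoperimetric
    lower bound 2*sqrt(pi) = 3.5449 reached by a circle.  Scale invariant.
    """
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon))
    if not poly.is_valid:
        raise FoamGeometryError("polygon is self-intersecting")
    if poly.area <= 0:
        raise FoamGeometryError("polygon has non-positive area")
    return float(poly.length / math.sqrt(poly.area))


@dataclass
class ShapeStats:
    """Per-compartment perimeter p (µm), area A (µm²), shape index s."""

    compartment_id: int
    perimeter: float
    area: float
    s: float


def network_shape_stats(net: FoamNetwork, interior_only: bool = True) -> pd.DataFrame:
    """Tidy table of compartment shape statistics.

    Boundary compartments are clipped artefacts and excluded by default.
    """
    ids = net.interior_compartments() if interior_only else range(len(net.compartments))
    rows = []
    for i in ids:
        poly = net.compartment_polygon(i)
        rows.append(
            ShapeStats(i, float(poly.length), float(poly.area), shape_index(poly))
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Tensions
# ---------------------------------------------------------------------------


@dataclass
class TensionState:
    """Tension state of the foam films.

    gamma_ml
        Monolayer (oil/water interface) tension, mN/m.
    gamma_b
        In-plane bilayer tension, mN/m; set by leaflet adhesion through
        gamma_b = 2 * gamma_ml * cos(phi).
    phi_deg
        Microscopic contact angle where the bilayer unzips into its two
        monolayers, degrees (0 <= phi < 90).
    gamma_c, delta_p, pipette_radius
        Critical aspiration tension (mN/m), suction pressure p1 - p0 (Pa)
        and pipette radius (µm) of the micropipette measurement.
    vertex_radius
        Optional curvature radius at the junction (µm); unresolved (dry
        limit) in most preparations.
    """

    gamma_ml: float
    gamma_b: float
    phi_deg: float
    gamma_c: float | None = None
    delta_p: float | None = None
    pipette_radius: float | None = None
    vertex_radius: float | None = None

    def __post_init__(self):
        if self.gamma_ml <= 0:
            raise FoamGeometryError("monolayer tension must be positive")
        if not (0 <= self.phi_deg < 90):
            raise FoamGeometryError("contact angle must be in [0, 90) degrees")
        if self.gamma_b > 2 * self.gamma_ml + 1e-12:
            raise FoamGeometryError("bilayer tension cannot exceed twice the monolayer tension")


def bilayer_tension(gamma_ml: float, phi_deg: float) -> float:
    """Bilayer tension from leaflet zipping: gamma_b = 2 gamma_ml cos(phi)."""
    if gamma_ml <= 0:
        raise FoamGeometryError("monolayer tension must be positive")
    if not (0 <= phi_deg < 90):
        raise FoamGeometryError("no zipped bilayer for contact angle outside [0, 90)")
    return 2.0 * gamma_ml * math.cos(math.radians(phi_deg))


def contact_angle(gamma_b: float, gamma_ml: float) -> float:
    """Microscopic contact angle (degrees) from the two tensions."""
    if gamma_ml <= 0 or gamma_b <= 0:
        raise FoamGeometryError("tensions must be positive")
    ratio = gamma_b / (2.0 * gamma_ml)
    if ratio > 1.0 + 1e-12:
        raise FoamGeometryError("gamma_b > 2 gamma_ml is unphysical")
    return math.degrees(math.acos(min(ratio, 1.0)))


def aspiration_tension(delta_p: float, pipette_radius: float, geometry_factor: float = 0.5) -> float:
    """Membrane tension (mN/m) from micropipette aspiration via the Laplace law.

    ``gamma_c = geometry_factor * |delta_p| * Rp`` with the default factor 1/2
    for a hemispherical cap spanning the pipette mouth.  ``delta_p`` in Pa,
    ``pipette_radius`` in µm.
    """
    if pipette_radius <= 0:
        raise FoamGeometryError("pipette radius must be positive")
    # Pa * µm = 1e-6 N/m = 1e-3 mN/m
    return geometry_factor * abs(delta_p) * pipette_radius * 1e-3


@dataclass
class StabilityClass:
    ratio: float
    label: str


def stability_ratios(gamma_b: float, gamma_ml: float) -> StabilityClass:
    """Classify the packing by the tension ratio gamma_b / gamma_ml.

    Below 0.23 the foam cannot maintain a confluent packing; between 0.23
    and 2 it is confluent and jammed; the ratio 2 (fully zipped limit)
    marks the rigidity transition of the equivalent vertex model.
    """
    if gamma_b <= 0 or gamma_ml <= 0:
        raise FoamGeometryError("tensions must be positive")
    ratio = gamma_b / gamma_ml
    if ratio < CONFLUENCE_RATIO:
        label = "sub-confluent"
    elif ratio < RIGIDITY_RATIO:
        label = "confluent-jammed"
    else:
        label = "at/above rigidity transition"
    return StabilityClass(ratio, label)


# ---------------------------------------------------------------------------
# Vertex force balance and relaxation
# ---------------------------------------------------------------------------


def vertex_net_force(
    net: FoamNetwork, edge_tensions: dict[tuple[int, int], float], vertex: int
) -> np.ndarray:
    """Net line-tension force on a junction.

    Sum over incident edges of (tension) x (unit vector from the vertex
    toward the opposite endpoint).  Zero at a balanced three-way junction;
    for boundary vertices (degree < 3) the partial sum is still returned.
    """
    x = net.vertices[vertex]
    f = np.zeros(2)
    for nb in net.neighbors(vertex):
        u = net.vertices[nb] - x
        L = np.linalg.norm(u)
        if L <= 0:
            raise FoamGeometryError("zero-length edge at vertex")
        f += edge_tensions[_edge_key(vertex, nb)] * u / L
    return f


def _junction_energy(x: np.ndarray, pins: np.ndarray, tensions: np.ndarray) -> float:
    return float(np.sum(tensions * np.linalg.norm(pins - x, axis=1)))


def relax_junction(
    pins,
    tensions,
    x0=None,
    step: float = None,
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> np.ndarray:
    """Equilibrium position of a junction with pinned far endpoints.

    Minimises the tension-weighted total edge length E = sum_i gamma_i L_i
    (the generalised Fermat point) by gradient descent with backtracking,
    so the energy never increases.  If one tension dominates the other
    two, the minimum sits at that pin and is returned directly (the
    subgradient condition |sum_{j != i} gamma_j u_j| <= gamma_i).
    """
    pins = np.asarray(pins, dtype=float)
    tensions = np.asarray(tensions, dtype=float)
    if pins.shape[0] != tensions.shape[0]:
        raise FoamGeometryError("one tension per pinned edge required")
    if np.any(tensions <= 0):
        raise FoamGeometryError("tensions must be positive")
    # pinned minimum check
    for i in range(len(pins)):
        others = [j for j in range(len(pins)) if j != i]
        pull = np.zeros(2)
        for j in others:
            u = pins[j] - pins[i]
            n = np.linalg.norm(u)
            if n > 0:
                pull += tensions[j] * u / n
        if np.linalg.norm(pull) <= tensions[i]:
            return pins[i].copy()
    x = np.average(pins, axis=0, weights=tensions) if x0 is None else np.asarray(x0, float)
    scale = float(np.mean(np.linalg.norm(pins - pins.mean(axis=0), axis=1)))
    s = step if step is not None else 0.1 * scale / float(tensions.sum())
    e = _junction_energy(x, pins, tensions)
    for it in range(max_iter):
        d = pins - x
        L = np.linalg.norm(d, axis=1)
        if np.any(L < 1e-12 * scale):
            break
        grad = -np.sum((tensions / L)[:, None] * d, axis=0)
        gnorm = np.linalg.norm(grad)
        if gnorm * s < tol:
            return x
        while s * gnorm > tol / 4:
            x_new = x - s * grad
            e_new = _junction_energy(x_new, pins, tensions)
            if e_new <= e:
                break
            s *= 0.5
        else:
            return x
        x, e = x_new, e_new
        s *= 1.2
    else:
        raise RelaxationError(
            f"no convergence after {max_iter} iterations (|grad|={gnorm:.3e}, step={s:.3e})"
        )
    return x


def relax_vertex(
    net: FoamNetwork,
    edge_tensions: dict[tuple[int, int], float],
    vertex: int,
    step: float = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Equilibrium position of *vertex* with its three neighbours pinned."""
    nbs = net.neighbors(vertex)
    if len(nbs) != 3:
        raise FoamGeometryError("relaxation requires a degree-3 vertex")
    pins = np.array([net.vertices[n] for n in nbs])
    tensions = np.array([edge_tensions[_edge_key(vertex, n)] for n in nbs])
    return relax_junction(pins, tensions, x0=net.vertices[vertex], step=step, tol=tol)


def junction_angles(x, pins) -> np.ndarray:
    """The three inter-edge angles (degrees) at a junction position."""
    x = np.asarray(x, float)
    pins = np.asarray(pins, float)
    ang = np.array([math.atan2(*(p - x)[::-1]) for p in pins])
    order = np.argsort(ang)
    ang = ang[order]
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * math.pi]]))
    return np.degrees(gaps)


# ---------------------------------------------------------------------------
# T1 transitions
# ---------------------------------------------------------------------------


@dataclass
class T1Event:
    """A detected neighbour-exchange: *edge* collapsed at *time*."""

    edge: tuple[int, int]
    time: float
    min_length: float
    compartments: tuple[int, ...] = ()


def detect_T1(
    times,
    edge_lengths: dict[tuple[int, int], np.ndarray],
    collapse_threshold: float,
    net: FoamNetwork | None = None,
) -> list[T1Event]:
    """Find edge-collapse events in edge-length time series.

    An event is reported when an edge's length falls below
    ``collapse_threshold`` and subsequently re-grows above it (the
    re-expansion of the reconnected edge).  Missing frames (NaN) split the
    search into contiguous runs.  If *net* is given each event carries the
    four compartments involved (two flanking, two end).
    """
    times = np.asarray(times, dtype=float)
    events: list[T1Event] = []
    if collapse_threshold <= 0:
        return events
    for edge, series in edge_lengths.items():
        series = np.asarray(series, dtype=float)
        valid = np.isfinite(series)
        idx = np.flatnonzero(valid)
        if idx.size == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            s = series[run]
            below = s < collapse_threshold
            if not below.any():
                continue
            first = int(np.argmax(below))
            # re-growth after the sub-threshold excursion
            after = s[first:]
            rise = np.flatnonzero(after >= collapse_threshold)
            if rise.size == 0:
                continue
            seg = after[: rise[0]]
            t_idx = run[first + int(np.argmin(seg))]
            comps: tuple[int, ...] = ()
            if net is not None:
                flank = net.compartments_of_edge(edge)
                a, b = edge
                ends = [
                    i
                    for i in set(net.compartments_of_vertex(a)) ^ set(net.compartments_of_vertex(b))
                ]
                comps = tuple(flank + ends)
            events.append(
                T1Event(edge, float(times[t_idx]), float(np.min(seg)), comps)
            )
    return events


def _cycle_neighbor(cycle: list[int], v: int, exclude: int) -> int:
    i = cycle.index(v)
    n = len(cycle)
    prev, nxt = cycle[i - 1], cycle[(i + 1) % n]
    return nxt if prev == exclude else prev


def apply_T1(net: FoamNetwork, edge: tuple[int, int]) -> FoamNetwork:
    """Apply a T1 neighbour exchange across *edge* and return a new network.

    The two compartments flanking the edge become second neighbours and
    the two end compartments (touching only one endpoint each) become
    edge-sharing; the edge itself is rotated 90 degrees about its
    midpoint.  Degree-3 connectivity and the compartment count are
    preserved, and applying the operator twice restores the topology.
    """
    a, b = edge
    edge = _edge_key(a, b)
    if edge not in net.edges:
        raise FoamGeometryError(f"{edge} is not an edge")
    a, b = edge
    flank = net.compartments_of_edge(edge)
    comps_a = set(net.compartments_of_vertex(a))
    comps_b = set(net.compartments_of_vertex(b))
    end_a = comps_a - comps_b
    end_b = comps_b - comps_a
    if len(flank) != 2 or len(end_a) != 1 or len(end_b) != 1:
        raise FoamGeometryError("T1 requires an interior edge with four distinct compartments")
    P, Q = flank
    A, B = end_a.pop(), end_b.pop()

    out = net.copy()
    cp, cq = out.compartments[P], out.compartments[Q]
    pa = _cycle_neighbor(cp, a, b)
    pb = _cycle_neighbor(cp, b, a)
    qa = _cycle_neighbor(cq, a, b)
    qb = _cycle_neighbor(cq, b, a)

    out.edges.discard(_edge_key(a, qa))
    out.edges.discard(_edge_key(b, pb))
    out.edges.add(_edge_key(a, pb))
    out.edges.add(_edge_key(b, qa))

    cp.remove(b)
    cq.remove(a)
    ca = out.compartments[A]
    i = ca.index(a)
    n = len(ca)
    if ca[i - 1] == qa:
        ca.insert(i, b)
    elif ca[(i + 1) % n] == qa:
        ca.insert(i + 1, b)
    else:  # pragma: no cover - inconsistent cycles
        raise FoamGeometryError("inconsistent compartment cycles at T1 edge")
    cb = out.compartments[B]
    i = cb.index(b)
    n = len(cb)
    if cb[i - 1] == pb:
        cb.insert(i, a)
    elif cb[(i + 1) % n] == pb:
        cb.insert(i + 1, a)
    else:  # pragma: no cover
        raise FoamGeometryError("inconsistent compartment cycles at T1 edge")

    # rotate the edge 90 degrees about its midpoint, orienting the new edge so
    # that a lands on the side of compartment P (which keeps a) and b on Q's
    xa, xb = out.vertices[a], out.vertices[b]
    mid = (xa + xb) / 2
    rot = np.array([[0.0, -1.0], [1.0, 0.0]])
    new_a = mid + rot @ (xa - mid)
    new_b = mid + rot @ (xb - mid)
    cp_centroid = net.compartment_centroid(P)
    if np.linalg.norm(new_a - cp_centroid) > np.linalg.norm(new_b - cp_centroid):
        new_a, new_b = new_b, new_a
    out.vertices[a] = new_a
    out.vertices[b] = new_b
    return out


def tension_hessian(
    net: FoamNetwork,
    edge_tensions: dict[tuple[int, int], float],
    area_stiffness: float = 0.0,
) -> tuple[np.ndarray, list[int]]:
    """Stiffness matrix of the foam energy over the free junctions.

    Hessian (N/m) of E = sum_e T_e L_e + sum_c (K_A/2)(A_c - A_c0)^2
    with boundary vertices pinned, evaluated at the current positions
    (taken as the reference, A = A0); dof ordering is (x, y) per free
    vertex in sorted-id order.  Each edge contributes the transverse
    block (T/L)(I - u u^T); each compartment the rank-one area block
    K_A (grad A)(grad A)^T.  The line-tension part alone is floppy
    (rank <= one per edge); the area term models the incompressibility
    of the aqueous compartments and rigidifies the network.  Positions
    are converted from µm to m, so H (N/m) multiplies displacements in
    metres; ``area_stiffness`` is in N/m^3.
    """
    free = [v for v in sorted(net.vertices) if v not in net.boundary]
    index = {v: i for i, v in enumerate(free)}
    H = np.zeros((2 * len(free), 2 * len(free)))
    for a, b in net.edges:
        u = net.vertices[b] - net.vertices[a]
        L = np.linalg.norm(u)
        if L <= 0:
            raise FoamGeometryError(f"zero-length edge {(a, b)}")
        uh = u / L
        blk = edge_tensions[_edge_key(a, b)] / (L * 1e-6) * (np.eye(2) - np.outer(uh, uh))
        for v, w, sign in ((a, a, 1), (b, b, 1), (a, b, -1), (b, a, -1)):
            if v in index and w in index:
                i, j = 2 * index[v], 2 * index[w]
                H[i : i + 2, j : j + 2] += sign * blk
    if area_stiffness > 0:
        for cyc in net.compartments:
            g = np.zeros(2 * len(free))
            n = len(cyc)
            for k, v in enumerate(cyc):
                if v not in index:
                    continue
                nxt = net.vertices[cyc[(k + 1) % n]] * 1e-6
                prv = net.vertices[cyc[k - 1]] * 1e-6
                g[2 * index[v]] = 0.5 * (nxt[1] - prv[1])
                g[2 * index[v] + 1] = 0.5 * (prv[0] - nxt[0])
            H += area_stiffness * np.outer(g, g)
    return H, free


def compartment_adjacency(net: FoamNetwork) -> dict[int, set[int]]:
    """Compartment neighbour sets recomputed from shared edges."""
    adj: dict[int, set[int]] = {i: set() for i in range(len(net.compartments))}
    owners: dict[tuple[int, int], list[int]] = {}
    for i, cyc in enumerate(net.compartments):
        n = len(cyc)
        for j in range(n):
            owners.setdefault(_edge_key(cyc[j], cyc[(j + 1) % n]), []).append(i)
    for cs in owners.values():
        for i in cs:
            for j in cs:
                if i != j:
                    adj[i].add(j)
    return adj
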