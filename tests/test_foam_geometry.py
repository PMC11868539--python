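import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import Polygon

import lipidfoam as lf
from lipidfoam.foam_geometry import FoamGeometryError, tension_hessian


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


class TestHexagonalLattice:
    def test_single_hexagon_geometry(self):
        net = lf.build_hexagonal_lattice(1, 1, 10.0)
        poly = net.compartment_polygon(0)
        assert poly.length == pytest.approx(60.0)
        assert poly.area == pytest.approx(1.5 * math.sqrt(3) * 100, rel=1e-9)

    def test_interior_vertices_are_threefold_120_degrees(self):
        net = lf.build_hexagonal_lattice(3, 3, 10.0)
        net.validate()
        assert len(net.compartments) == 9
        for v in net.interior_vertices():
            assert net.degree(v) == 3
            pins = [net.vertices[n] for n in net.neighbors(v)]
            assert lf.junction_angles(net.vertices[v], pins) == pytest.approx(
                [120.0] * 3, abs=1e-6
            )

    @pytest.mark.parametrize("shape", [(1, 1), (3, 3), (2, 5)])
    def test_interior_shape_index_is_hexagonal_reference(self, shape):
        net = lf.build_hexagonal_lattice(*shape, 10.0)
        for i in range(len(net.compartments)):
            assert lf.shape_index(net.compartment_polygon(i)) == pytest.approx(
                3.722, abs=1e-3
            )

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(FoamGeometryError):
            lf.build_hexagonal_lattice(0, 3, 10.0)
        with pytest.raises(FoamGeometryError):
            lf.build_hexagonal_lattice(3, 3, -1.0)


class TestDisorderedFoam:
    def test_zero_disorder_reduces_to_honeycomb(self):
        net = lf.build_disordered_foam(64, 0.0, seed=1)
        net.validate()
        stats = lf.network_shape_stats(net)
        assert stats.s.mean() == pytest.approx(3.722, abs=1e-3)
        for v in net.interior_vertices():
            assert net.degree(v) == 3

    def test_moderate_disorder_matches_experimental_shape_range(self):
        # calibrated regime of centrifugation-prepared foams
        net = lf.build_disordered_foam(100, 0.3, seed=2)
        net.validate()
        assert 3.75 <= lf.network_shape_stats(net).s.mean() <= 3.85

    def test_same_seed_reproduces_network(self):
        a = lf.build_disordered_foam(50, 0.3, seed=9)
        b = lf.build_disordered_foam(50, 0.3, seed=9)
        assert a.to_json() == b.to_json()


# ---------------------------------------------------------------------------
# shape index
# ---------------------------------------------------------------------------


class TestShapeIndex:
    def test_reference_polygons(self):
        hexagon = [(math.cos(t), math.sin(t)) for t in np.arange(6) * math.pi / 3]
        assert lf.shape_index(hexagon) == pytest.approx(3.7224, abs=1e-3)
        assert lf.shape_index([(0, 0), (1, 0), (1, 1), (0, 1)]) == pytest.approx(4.0)
        circle = [(math.cos(t), math.sin(t)) for t in np.linspace(0, 2 * math.pi, 361)[:-1]]
        assert lf.shape_index(circle) == pytest.approx(2 * math.sqrt(math.pi), abs=1e-3)

    @given(st.floats(min_value=1e-3, max_value=1e3), st.integers(min_value=3, max_value=12))
    def test_scale_invariance(self, lam, n):
        poly = [(math.cos(t), math.sin(t)) for t in np.arange(n) * 2 * math.pi / n]
        scaled = [(lam * x, lam * y) for x, y in poly]
        assert lf.shape_index(scaled) == pytest.approx(lf.shape_index(poly), rel=1e-9)

    def test_rejects_self_intersecting_polygon(self):
        with pytest.raises(FoamGeometryError):
            lf.shape_index([(0, 0), (1, 1), (1, 0), (0, 1)])  # bow tie


# ---------------------------------------------------------------------------
# tensions
# ---------------------------------------------------------------------------


class TestTensionRelations:
    @pytest.mark.parametrize(
        "gamma_ml,phi,expected",
        [(1.0, 0.0, 2.0), (1.0, 60.0, 1.0), (1.0, 40.0, 1.532)],
    )
    def test_bilayer_tension_examples(self, gamma_ml, phi, expected):
        assert lf.bilayer_tension(gamma_ml, phi) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize(
        "gamma_b,gamma_ml,expected",
        [(2.0, 1.0, 0.0), (1.532, 1.0, 40.0), (1.231, 1.0, 52.0)],
    )
    def test_contact_angle_examples(self, gamma_b, gamma_ml, expected):
        assert lf.contact_angle(gamma_b, gamma_ml) == pytest.approx(expected, abs=0.1)

    @given(
        st.floats(min_value=0.01, max_value=10.0),
        st.floats(min_value=0.0, max_value=89.0),
    )
    def test_round_trip(self, gamma_ml, phi):
        assert lf.contact_angle(
            lf.bilayer_tension(gamma_ml, phi), gamma_ml
        ) == pytest.approx(phi, rel=1e-9, abs=1e-7)

    def test_unphysical_inputs_rejected(self):
        with pytest.raises(FoamGeometryError):
            lf.bilayer_tension(1.0, 95.0)
        with pytest.raises(FoamGeometryError):
            lf.contact_angle(2.5, 1.0)

    def test_aspiration_tension(self):
        assert lf.aspiration_tension(0.0, 2.0) == 0.0
        assert lf.aspiration_tension(3000.0, 2.0) == pytest.approx(3.0)
        assert lf.aspiration_tension(-3000.0, 4.0) == pytest.approx(
            2 * lf.aspiration_tension(3000.0, 2.0)
        )

    @pytest.mark.parametrize(
        "ratio,label",
        [
            (0.1, "sub-confluent"),
            (1.5, "confluent-jammed"),
            (2.0, "at/above rigidity transition"),
        ],
    )
    def test_stability_classification(self, ratio, label):
        res = lf.stability_ratios(ratio, 1.0)
        assert res.ratio == pytest.approx(ratio)
        assert res.label == label


# ---------------------------------------------------------------------------
# force balance and relaxation
# ---------------------------------------------------------------------------


def _star_net(pins, tensions):
    vertices = {0: np.array([2.0, 1.0])}
    edges = set()
    tmap = {}
    for i, (p, t) in enumerate(zip(pins, tensions), start=1):
        vertices[i] = np.asarray(p, dtype=float)
        edges.add((0, i))
        tmap[(0, i)] = t
    net = lf.FoamNetwork(vertices, edges, [], boundary=set(range(1, len(pins) + 1)))
    return net, tmap


class TestVertexForce:
    def test_symmetric_junction_is_balanced(self):
        pins = [(10 * math.cos(t), 10 * math.sin(t)) for t in np.deg2rad([0, 120, 240])]
        net, tmap = _star_net(pins, [1.0] * 3)
        net.vertices[0] = np.zeros(2)
        assert np.linalg.norm(lf.vertex_net_force(net, tmap, 0)) < 1e-12

    def test_force_restores_toward_balance(self):
        pins = [(10 * math.cos(t), 10 * math.sin(t)) for t in np.deg2rad([0, 120, 240])]
        net, tmap = _star_net(pins, [1.0] * 3)
        net.vertices[0] = np.array([1.0, 0.5])
        f = lf.vertex_net_force(net, tmap, 0)
        assert np.dot(f, -net.vertices[0]) > 0

    def test_unequal_tensions_against_brute_force_sum(self):
        pins = [(10, 0), (-5, 8.66), (-5, -8.66)]
        tensions = [2.0, 1.0, 1.0]
        net, tmap = _star_net(pins, tensions)
        net.vertices[0] = np.array([0.5, -0.2])
        expected = np.zeros(2)
        for p, t in zip(pins, tensions):
            u = np.asarray(p, float) - net.vertices[0]
            expected += t * u / np.linalg.norm(u)
        assert lf.vertex_net_force(net, tmap, 0) == pytest.approx(expected)


class TestRelaxation:
    def test_equal_tensions_give_120_degrees(self):
        pins = np.array([[0.0, 0.0], [20.0, 3.0], [8.0, 18.0]])
        x = lf.relax_junction(pins, [1.0, 1.0, 1.0])
        assert lf.junction_angles(x, pins) == pytest.approx([120.0] * 3, abs=0.5)

    def test_dominant_tension_pulls_vertex_onto_pin(self):
        pins = np.array([[0.0, 0.0], [20.0, 3.0], [8.0, 18.0]])
        x = lf.relax_junction(pins, [100.0, 1.0, 1.0])
        assert x == pytest.approx(pins[0], abs=1e-9)

    def test_matches_brute_force_grid_minimum(self):
        pins = np.array([[0.0, 0.0], [20.0, 3.0], [8.0, 18.0]])
        tensions = np.array([1.0, 1.3, 0.8])
        x = lf.relax_junction(pins, tensions)
        gx, gy = np.meshgrid(np.arange(0, 20, 0.01), np.arange(0, 18, 0.01))
        energy = sum(
            t * np.hypot(gx - p[0], gy - p[1]) for p, t in zip(pins, tensions)
        )
        k = np.unravel_index(np.argmin(energy), energy.shape)
        best = np.array([gx[k], gy[k]])
        assert np.linalg.norm(best - x) < 0.02  # within grid resolution

    def test_relax_vertex_on_network(self, hex_net, uniform_tensions):
        v = hex_net.interior_vertices()[0]
        pins = [hex_net.vertices[n] for n in hex_net.neighbors(v)]
        x = lf.relax_vertex(hex_net, uniform_tensions, v)
        assert lf.junction_angles(x, pins) == pytest.approx([120.0] * 3, abs=0.5)


# ---------------------------------------------------------------------------
# T1 transitions
# ---------------------------------------------------------------------------


def _interior_t1_edge(net):
    for e in sorted(net.edges):
        a, b = e
        ca = set(net.compartments_of_vertex(a))
        cb = set(net.compartments_of_vertex(b))
        if len(net.compartments_of_edge(e)) == 2 and len(ca - cb) == 1 and len(cb - ca) == 1:
            return e
    raise AssertionError("no interior T1 edge in fixture")


class TestApplyT1:
    def test_neighbor_swap(self, hex_net):
        e = _interior_t1_edge(hex_net)
        a, b = e
        P, Q = hex_net.compartments_of_edge(e)
        A = (set(hex_net.compartments_of_vertex(a)) - set(hex_net.compartments_of_vertex(b))).pop()
        B = (set(hex_net.compartments_of_vertex(b)) - set(hex_net.compartments_of_vertex(a))).pop()
        adj0 = lf.compartment_adjacency(hex_net)
        swapped = lf.apply_T1(hex_net, e)
        swapped.validate()
        adj1 = lf.compartment_adjacency(swapped)
        assert Q in adj0[P] and Q not in adj1[P]
        assert B not in adj0[A] and B in adj1[A]

    def test_involution_and_conservation(self, hex_net):
        e = _interior_t1_edge(hex_net)
        twice = lf.apply_T1(lf.apply_T1(hex_net, e), e)
        assert twice.edges == hex_net.edges
        assert lf.compartment_adjacency(twice) == lf.compartment_adjacency(hex_net)
        assert len(twice.compartments) == len(hex_net.compartments)

    def test_euler_characteristic_preserved(self, hex_net):
        e = _interior_t1_edge(hex_net)
        swapped = lf.apply_T1(hex_net, e)
        chi0 = len(hex_net.vertices) - len(hex_net.edges) + len(hex_net.compartments)
        chi1 = len(swapped.vertices) - len(swapped.edges) + len(swapped.compartments)
        assert chi0 == chi1

    def test_boundary_edge_rejected(self, hex_net):
        boundary_edge = next(
            e for e in sorted(hex_net.edges) if len(hex_net.compartments_of_edge(e)) == 1
        )
        with pytest.raises(FoamGeometryError):
            lf.apply_T1(hex_net, boundary_edge)


class TestDetectT1:
    def test_static_lattice_has_no_events(self, hex_net):
        times = np.arange(100.0)
        series = {e: np.full(100, hex_net.edge_length(e)) for e in hex_net.edges}
        assert lf.detect_T1(times, series, collapse_threshold=0.5) == []

    def test_scripted_collapse_detected_at_right_time(self, hex_net):
        e = _interior_t1_edge(hex_net)
        times = np.arange(100.0)
        L0 = hex_net.edge_length(e)
        lengths = np.full(100, L0)
        lengths[40:61] = np.abs(np.linspace(L0, -L0, 21))  # collapse and regrow
        events = lf.detect_T1(times, {e: lengths}, collapse_threshold=0.5, net=hex_net)
        assert len(events) == 1
        assert abs(events[0].time - 50.0) <= 1.0
        assert len(events[0].compartments) == 4

    def test_zero_threshold_never_fires(self, hex_net):
        e = _interior_t1_edge(hex_net)
        lengths = np.abs(np.sin(np.arange(100.0))) + 0.01
        assert lf.detect_T1(np.arange(100.0), {e: lengths}, collapse_threshold=0.0) == []

    def test_missing_frames_restrict_search_to_runs(self, hex_net):
        e = _interior_t1_edge(hex_net)
        lengths = np.full(100, 10.0)
        lengths[40:45] = 0.1  # collapse ...
        lengths[45:50] = np.nan  # ... but the regrowth frame is missing
        events = lf.detect_T1(np.arange(100.0), {e: lengths}, collapse_threshold=0.5)
        assert events == []


# ---------------------------------------------------------------------------
# serialisation and mechanics helpers
# ---------------------------------------------------------------------------


def test_network_json_round_trip(hex_net):
    back = lf.FoamNetwork.from_json(hex_net.to_json())
    assert back.edges == hex_net.edges
    assert back.boundary == hex_net.boundary
    assert back.compartments == hex_net.compartments
    for v in hex_net.vertices:
        assert back.vertices[v] == pytest.approx(hex_net.vertices[v])


def test_network_csv_round_trip(hex_net, tmp_path):
    hex_net.write(tmp_path / "net")
    back = lf.FoamNetwork.read(tmp_path / "net")
    assert back.edges == hex_net.edges
    assert back.compartments == hex_net.compartments


def test_tension_hessian_matches_finite_differences(hex_net, uniform_tensions):
    H, free = tension_hessian(hex_net, uniform_tensions, area_stiffness=3e4)
    # numeric Hessian of the same energy for a few dof
    def energy(disp):
        pos = {v: hex_net.vertices[v].copy() for v in hex_net.vertices}
        for i, v in enumerate(free):
            pos[v] = pos[v] + disp[2 * i : 2 * i + 2] * 1e6  # m -> µm
        e = sum(
            uniform_tensions[eid] * np.linalg.norm(pos[eid[0]] - pos[eid[1]]) * 1e-6
            for eid in hex_net.edges
        )
        for cyc in hex_net.compartments:
            pts = np.array([pos[v] for v in cyc]) * 1e-6
            area = 0.5 * np.sum(
                pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1]
            )
            pts0 = np.array([hex_net.vertices[v] for v in cyc]) * 1e-6
            area0 = 0.5 * np.sum(
                pts0[:, 0] * np.roll(pts0[:, 1], -1) - np.roll(pts0[:, 0], -1) * pts0[:, 1]
            )
            e += 0.5 * 3e4 * (area - area0) ** 2
        return e

    h = 1e-9
    rng = np.random.default_rng(0)
    for _ in range(4):
        i, j = rng.integers(0, H.shape[0], size=2)
        ei = np.zeros(H.shape[0]); ei[i] = h
        ej = np.zeros(H.shape[0]); ej[j] = h
        num = (energy(ei + ej) - energy(ei) - energy(ej) + energy(np.zeros_like(ei))) / h**2
        assert num == pytest.approx(H[i, j], rel=2e-3, abs=1e-9)
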