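"""Menger curvature, node/segment/connection descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastoquant import element_descriptors as ed
from plastoquant.gross_morphology import wrapped_hull
from plastoquant.pipeline import quantify_mask, segment_stack
from plastoquant.segmentation import BinaryMask
from plastoquant.spatial_graph import GraphNode, GraphSegment, SpatialGraph
from plastoquant.synthetic_networks import render_phantom, y_graph

finite = st.floats(-10, 10, allow_nan=False)


class TestMengerCurvature:
    def test_collinear_is_zero(self):
        assert ed.menger_curvature((0, 0, 0), (1, 0, 0), (2, 0, 0)) == 0.0

    def test_circle_of_radius_two(self):
        k = ed.menger_curvature((2, 0, 0), (0, 2, 0), (-2, 0, 0))
        assert k == pytest.approx(0.5, abs=1e-12)

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError):
            ed.menger_curvature((1, 1, 1), (1, 1, 1), (0, 0, 0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(*[finite] * 9)
    def test_equals_reciprocal_circumradius(self, ax, ay, az, bx, by, bz, cx, cy, cz):
        """Law-of-sines oracle: R = a / (2 sin A), Menger curvature = 1/R."""
        p1, p2, p3 = np.array([ax, ay, az]), np.array([bx, by, bz]), np.array([cx, cy, cz])
        a = np.linalg.norm(p3 - p2)
        b = np.linalg.norm(p3 - p1)
        c = np.linalg.norm(p2 - p1)
        if min(a, b, c) < 1e-3:
            return
        cosA = np.clip((b * b + c * c - a * a) / (2 * b * c), -1, 1)
        sinA = np.sqrt(1 - cosA ** 2)
        if sinA < 1e-8:
            expected = 0.0
        else:
            expected = 2 * sinA / a
        assert ed.menger_curvature(p1, p2, p3) == pytest.approx(expected, abs=1e-9)


def _manual_graph(node_specs, segment_specs, spacing=(0.24, 0.042, 0.042)):
    nodes = [GraphNode(i, np.asarray(p, float), th, kind)
             for i, (p, th, kind) in enumerate(node_specs)]
    segs = []
    for i, (a, b, pts, th) in enumerate(segment_specs):
        pts = np.asarray(pts, float)
        th = np.full(len(pts), th, float)
        segs.append(GraphSegment(i, (a, b), pts, th, np.zeros(len(pts), bool)))
    return SpatialGraph(nodes, segs, spacing)


def _ball_mask(center, r=0.3, spacing=(0.2, 0.1, 0.1), shape=(20, 42, 42)):
    sp = np.asarray(spacing)
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)],
                             indexing="ij")
    c = np.asarray(center)
    return BinaryMask(((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r ** 2,
                      tuple(sp))


class TestNodeDescriptors:
    def test_cube_corner_distances_match_brute_force(self):
        edge = 1.0
        corners = [(z, y, x) for z in (1, 1 + edge) for y in (1, 1 + edge)
                   for x in (1, 1 + edge)]
        node_specs = [(c, 100.0, "junction") for c in corners]
        # join consecutive corners so degrees exist; geometry irrelevant here
        seg_specs = [(i, (i + 1) % 8, [corners[i], corners[(i + 1) % 8]], 100.0)
                     for i in range(8)]
        graph = _manual_graph(node_specs, seg_specs)
        mask = _ball_mask((1.5, 1.5, 1.5), r=0.45)
        hull = wrapped_hull(mask)
        nd = ed.node_descriptors(graph, hull, mask)
        np.testing.assert_allclose(nd["d_nn_um"], edge, rtol=1e-9)
        # centre of gravity of the ball is the cube centre
        expected_dnc = np.linalg.norm(np.array([0.5] * 3) * edge)
        np.testing.assert_allclose(nd["d_nc_um"], expected_dnc, atol=0.02)
        # brute-force pairwise check
        pos = np.array(corners, float)
        brute = [min(np.linalg.norm(p - q) for j, q in enumerate(pos) if j != i)
                 for i, p in enumerate(pos)]
        np.testing.assert_allclose(nd["d_nn_um"], brute, rtol=1e-9)

    def test_compactness_from_printed_group_means(self):
        """C_PN = (d_nc - d_ns)/d_nc on the published mean distances."""
        d_nc, d_ns = 2.07, 0.57
        c = (d_nc - d_ns) / d_nc
        assert c == pytest.approx(0.7246, abs=1e-4)
        assert abs(c - 0.71) <= 0.09  # inside the published mean +/- SD

    def test_single_node_dnn_is_missing_not_zero(self):
        mask = _ball_mask((1.5, 1.5, 1.5))
        graph = _manual_graph([((1.5, 1.5, 1.5), 100.0, "open")], [])
        # a single open node with no segments
        nd = ed.node_descriptors(graph, wrapped_hull(mask), mask)
        assert np.isnan(nd["mean_d_nn"])

    def test_node_at_centre_of_gravity_excluded(self):
        mask = _ball_mask((2.0, 2.1, 2.1), r=0.5)
        cog = (np.argwhere(mask.voxels) + 0.5) @ np.diag(mask.spacing)
        cog = cog.mean(axis=0)
        graph = _manual_graph(
            [(cog, 100.0, "junction"), (cog + [0, 0.8, 0], 100.0, "open")],
            [(0, 1, [cog, cog + [0, 0.8, 0]], 100.0)])
        nd = ed.node_descriptors(graph, wrapped_hull(mask), mask)
        assert nd["excluded_at_centre"] == 1
        assert np.isfinite(nd["C_PN"])


class TestSegmentDescriptors:
    def test_straight_two_point_segment(self):
        graph = _manual_graph(
            [((1, 1, 1), 100.0, "open"), ((1, 1, 2), 100.0, "open")],
            [(0, 1, [(1, 1, 1), (1, 1, 2)], 100.0)])
        sd = ed.segment_descriptors(graph)
        assert sd["kappa_s"] == 0.0
        assert sd["I_s"] == 0.0
        assert sd["L_s"] == pytest.approx(1.0)

    def test_arc_curvature_exact(self):
        r = 2.0
        phi = np.linspace(-0.5, 0.5, 10)
        pts = np.column_stack([np.zeros_like(phi), r * np.sin(phi),
                               r * np.cos(phi)]) + [1, 3, 0]
        graph = _manual_graph(
            [(pts[0], 100.0, "open"), (pts[-1], 100.0, "open")],
            [(0, 1, pts, 100.0)])
        sd = ed.segment_descriptors(graph)
        assert sd["kappa_s"] == pytest.approx(0.5, abs=1e-6)

    def test_point_spacing_reported_in_nm(self):
        pts = np.array([[1, 1, 1 + 0.06 * i] for i in range(20)])
        graph = _manual_graph([(pts[0], 80.0, "open"), (pts[-1], 80.0, "open")],
                              [(0, 1, pts, 80.0)])
        sd = ed.segment_descriptors(graph)
        assert sd["d_pp"] == pytest.approx(60.0, abs=1.0)

    def test_discrete_curvature_bound(self):
        """kappa of any segment <= 2 / min consecutive-point spacing."""
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(0, 0.05, (30, 3)), axis=0) + 2.0
        graph = _manual_graph([(pts[0], 80.0, "open"), (pts[-1], 80.0, "open")],
                              [(0, 1, pts, 80.0)])
        sd = ed.segment_descriptors(graph, curvature_stride_um=0.01)
        min_step = np.linalg.norm(np.diff(pts, axis=0), axis=1).min()
        assert sd["kappa_s"] <= 2.0 / min_step + 1e-9


class TestConnectionDescriptors:
    def _star(self, angles_deg, center=(2.0, 2.0, 2.0), arm=1.0):
        center = np.asarray(center, float)
        node_specs = [(center, 120.0, "junction")]
        seg_specs = []
        for k, a in enumerate(angles_deg):
            d = np.array([0.0, np.sin(np.radians(a)), np.cos(np.radians(a))])
            pts = center + np.linspace(0, arm, 12)[:, None] * d
            node_specs.append((pts[-1], 120.0, "open"))
            seg_specs.append((0, k + 1, pts, 120.0))
        return _manual_graph(node_specs, seg_specs)

    def test_symmetric_y_mean_angle_120(self):
        cd = ed.connection_descriptors(self._star([90, 210, 330]))
        assert cd["theta_c3"] == pytest.approx(120.0, abs=1e-6)
        assert cd["n_c"] == pytest.approx(3.0)

    def test_orthogonal_plus_mean_angle_120(self):
        cd = ed.connection_descriptors(self._star([0, 90, 180, 270]))
        np.testing.assert_allclose(sorted(cd["angles4_deg"]),
                                   [90, 90, 90, 90, 180, 180], atol=1e-6)
        assert cd["theta_c4"] == pytest.approx(120.0, abs=1e-6)

    def test_open_node_percentage(self):
        graph = self._star([90, 210, 330])  # 1 junction + 3 open = 75%
        cd = ed.connection_descriptors(graph)
        assert cd["n_oe"] == pytest.approx(75.0)

    def test_no_junction_theta_missing(self):
        pts = np.array([[1, 1, 1], [1, 1, 2]], float)
        graph = _manual_graph([(pts[0], 80.0, "open"), (pts[-1], 80.0, "open")],
                              [(0, 1, pts, 80.0)])
        cd = ed.connection_descriptors(graph)
        assert np.isnan(cd["theta_c3"])
        assert cd["n_oe"] == 100.0


class TestSummarize:
    def test_y_phantom_summary_counts(self, config, clean_spec):
        img = render_phantom(y_graph(center=(2.0, 3.0, 3.0)), clean_spec)
        mask = segment_stack(img, config)
        s = quantify_mask(mask, config, image=img)
        assert s.scalars["N_n"] == 4
        assert s.scalars["N_s"] == 3
        assert s.scalars["n_oe"] == pytest.approx(75.0)
        assert s.scalars["theta_c3"] == pytest.approx(120.0, abs=6.0)

    def test_descriptors_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        angles = [80, 200, 320]
        g1 = TestConnectionDescriptors()._star(angles)
        # relabel: reverse node/segment order and flip a segment orientation
        nodes = [GraphNode(nid, n.position.copy(), n.thickness_nm, n.kind)
                 for nid, n in zip([3, 2, 1, 0], g1.nodes)]
        remap = {0: 3, 1: 2, 2: 1, 3: 0}
        segs = []
        for i, s in enumerate(reversed(g1.segments)):
            pts = s.points[::-1].copy()
            segs.append(GraphSegment(i, (remap[s.nodes[1]], remap[s.nodes[0]]),
                                     pts, s.thickness_nm[::-1].copy(),
                                     s.change_flags[::-1].copy()))
        g2 = SpatialGraph(nodes, segs, g1.spacing)
        cd1, cd2 = ed.connection_descriptors(g1), ed.connection_descriptors(g2)
        assert cd1["theta_c3"] == pytest.approx(cd2["theta_c3"], abs=1e-9)
        sd1, sd2 = ed.segment_descriptors(g1), ed.segment_descriptors(g2)
        assert sorted(sd1["length_um"]) == pytest.approx(sorted(sd2["length_um"]))
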