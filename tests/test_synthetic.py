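"""Phantom generator: determinism, exact counts, arc geometry, rendering."""

import numpy as np
import pytest

from plastoquant.synthetic_networks import (GroundTruthGraph, InfeasibleSpecError,
                                            PhantomSpec, arc_points,
                                            ground_truth_descriptors, rasterize,
                                            render_phantom, sample_ground_truth,
                                            tube_graph, y_graph)

from conftest import SMALL_STATS


class TestSampling:
    def test_exact_junction_and_endpoint_counts(self):
        spec = PhantomSpec(seed=11, **SMALL_STATS)
        g = sample_ground_truth(spec)
        junctions = [n for n in g.nodes if n.kind in ("junction", "meganode")]
        endpoints = [n for n in g.nodes if n.kind == "endpoint"]
        assert len(junctions) == spec.n_junctions
        assert len(endpoints) == spec.n_open
        for n in junctions:
            assert g.degree(n.id) in (3, 4)
        for n in endpoints:
            assert g.degree(n.id) == 1

    def test_same_seed_identical_different_seed_differs(self):
        spec1 = PhantomSpec(seed=1, **SMALL_STATS)
        g1 = sample_ground_truth(spec1)
        g2 = sample_ground_truth(PhantomSpec(seed=1, **SMALL_STATS))
        g3 = sample_ground_truth(PhantomSpec(seed=2, **SMALL_STATS))
        for a, b in zip(g1.nodes, g2.nodes):
            np.testing.assert_array_equal(a.position, b.position)
        assert any(not np.allclose(a.position, b.position)
                   for a, b in zip(g1.nodes, g3.nodes))

    def test_junction_free_spec_gives_single_open_filament(self):
        spec = PhantomSpec(seed=4, n_junctions=0, n_open=2)
        g = sample_ground_truth(spec)
        assert len(g.segments) == 1
        assert sorted(n.kind for n in g.nodes) == ["endpoint", "endpoint"]

    def test_infeasible_specs_raise(self):
        with pytest.raises(InfeasibleSpecError):
            sample_ground_truth(PhantomSpec(seed=0, n_junctions=500,
                                            domain_um=(2.0, 2.0, 2.0)))
        with pytest.raises(InfeasibleSpecError):
            sample_ground_truth(PhantomSpec(seed=0, n_junctions=0, n_open=4))

    def test_meganode_fraction_applied(self):
        spec = PhantomSpec(seed=2, meganode_fraction=0.1, **SMALL_STATS)
        g = sample_ground_truth(spec)
        megas = [n for n in g.nodes if n.kind == "meganode"]
        assert len(megas) == round(0.1 * spec.n_junctions)
        lo, hi = spec.meganode_diameter_nm
        for m in megas:
            assert lo <= 2 * m.radius_nm <= hi

    def test_graph_is_connected(self):
        import networkx as nx
        g = sample_ground_truth(PhantomSpec(seed=7, **SMALL_STATS))
        assert nx.is_connected(g.to_networkx())


class TestArcGeometry:
    def test_zero_bow_is_straight_chord(self):
        pts, kappa, length = arc_points(np.zeros(3), np.array([0, 0, 2.0]),
                                        np.array([0, 1, 0]), 0.0)
        assert kappa == 0.0
        assert length == pytest.approx(2.0)

    def test_sagitta_relation_gives_exact_curvature(self):
        c, h = 2.0, 0.2
        pts, kappa, length = arc_points(np.zeros(3), np.array([0, 0, c]),
                                        np.array([0, 1, 0]), h)
        r_expected = h / 2 + c * c / (8 * h)
        assert kappa == pytest.approx(1 / r_expected, rel=1e-12)
        # every interior triplet of the polyline sits on that circle
        from plastoquant.element_descriptors import menger_curvature
        k = menger_curvature(pts[1], pts[len(pts) // 2], pts[-2])
        assert k == pytest.approx(kappa, rel=1e-6)

    def test_arc_of_radius_two_has_curvature_half(self):
        # bow height for R=2 and chord 2: h = R - sqrt(R^2 - c^2/4)
        c = 2.0
        h = 2.0 - np.sqrt(4.0 - 1.0)
        _, kappa, _ = arc_points(np.zeros(3), np.array([0, 0, c]),
                                 np.array([0, 1, 0]), h)
        assert kappa == pytest.approx(0.5, rel=1e-12)


class TestRendering:
    def test_cylinder_rasterizes_as_discs(self):
        spec = PhantomSpec(seed=0, domain_um=(2.0, 2.0, 4.0),
                           spacing=(0.1, 0.1, 0.1))
        g = tube_graph(length_um=3.0, radius_nm=300.0, center=(1.05, 1.05, 2.0))
        mask = rasterize(g, spec)
        mid = mask.voxels[:, :, 20]
        # disc of radius 3 voxels around the axis
        assert mid.sum() == ((np.add.outer((np.arange(20) + 0.5 - 10.5) ** 2,
                                           (np.arange(20) + 0.5 - 10.5) ** 2))
                             <= 9.0).sum()

    def test_tube_volume_conservation(self):
        """Rasterized volume within 10% of pi r^2 L for r >= 3 in-plane voxels."""
        spec = PhantomSpec(seed=0, domain_um=(3.0, 3.0, 5.0),
                           spacing=(0.24, 0.05, 0.05))
        r_um, length = 0.3, 3.5
        g = tube_graph(length_um=length, radius_nm=r_um * 1e3, center=(1.5, 1.5, 2.5))
        mask = rasterize(g, spec)
        analytic = np.pi * r_um ** 2 * length
        assert mask.count() * mask.voxel_volume == pytest.approx(analytic, rel=0.10)

    def test_noiseless_render_seed_independent(self):
        base = dict(SMALL_STATS)
        g = sample_ground_truth(PhantomSpec(seed=5, **base))
        img1 = render_phantom(g, PhantomSpec(seed=5, snr=None, **base))
        img2 = render_phantom(g, PhantomSpec(seed=99, snr=None, **base))
        np.testing.assert_array_equal(img1.intensities, img2.intensities)

    def test_noisy_render_depends_on_seed(self):
        base = dict(SMALL_STATS)
        g = sample_ground_truth(PhantomSpec(seed=5, **base))
        img1 = render_phantom(g, PhantomSpec(seed=5, **base))
        img2 = render_phantom(g, PhantomSpec(seed=6, **base))
        assert not np.array_equal(img1.intensities, img2.intensities)

    def test_subresolution_radius_warns(self):
        spec = PhantomSpec(seed=0, domain_um=(2.0, 2.0, 3.0),
                           spacing=(0.24, 0.1, 0.1))
        g = tube_graph(length_um=2.0, radius_nm=50.0, center=(1.0, 1.0, 1.5))
        with pytest.warns(UserWarning, match="sub-resolution"):
            rasterize(g, spec)


class TestGroundTruthDescriptors:
    def test_symmetric_y_angles_and_open_fraction(self):
        spec = PhantomSpec(seed=0)
        truth = ground_truth_descriptors(y_graph(center=(2.0, 3.0, 3.0)), spec)
        assert truth.scalars["theta_c3"] == pytest.approx(120.0, abs=0.5)
        assert truth.scalars["n_oe"] == pytest.approx(75.0)
        assert truth.scalars["N_n"] == 4
        assert truth.scalars["N_s"] == 3

    def test_single_filament_open_percentage_100(self):
        spec = PhantomSpec(seed=0)
        truth = ground_truth_descriptors(
            tube_graph(length_um=2.0, center=(2.0, 3.0, 3.0)), spec)
        assert truth.scalars["n_oe"] == 100.0

    def test_arc_segment_curvature_is_reciprocal_radius(self):
        spec = PhantomSpec(seed=0)
        c = 2.0
        h = 2.0 - np.sqrt(4.0 - 1.0)  # R = 2 um
        pts, kappa, length = arc_points(np.array([2, 3, 2.0]), np.array([2, 3, 4.0]),
                                        np.array([0, 1, 0]), h)
        from plastoquant.synthetic_networks import GTNode, GTSegment
        g = GroundTruthGraph(
            [GTNode(0, pts[0], 60.0, "endpoint"), GTNode(1, pts[-1], 60.0, "endpoint")],
            [GTSegment(0, pts, np.full(len(pts), 60.0), (0, 1), kappa, length)])
        truth = ground_truth_descriptors(g, spec)
        assert truth.scalars["kappa_s"] == pytest.approx(0.5, rel=1e-9)

    def test_json_round_trip(self, tmp_path):
        g = sample_ground_truth(PhantomSpec(seed=3, **SMALL_STATS))
        g.to_json(tmp_path / "g.json")
        back = GroundTruthGraph.from_json(tmp_path / "g.json")
        assert len(back.nodes) == len(g.nodes)
        for a, b in zip(g.segments, back.segments):
            np.testing.assert_allclose(a.points, b.points)
            assert a.curvature_per_um == b.curvature_per_um
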