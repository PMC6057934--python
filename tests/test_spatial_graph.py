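"""Distance map, skeletonization and graph extraction."""

import numpy as np
import pytest

from plastoquant import spatial_graph as sg
from plastoquant.pipeline import segment_stack
from plastoquant.segmentation import BinaryMask
from plastoquant.synthetic_networks import (PhantomSpec, render_phantom,
                                            torus_graph, tube_graph, y_graph)

from conftest import CLEAN_RENDER


def _brute_force_edt(vox, spacing):
    """Nearest-background scan with the volume border counted as background."""
    vox = np.asarray(vox, bool)
    sp = np.asarray(spacing)
    padded = np.pad(vox, 1, constant_values=False)
    bg = np.argwhere(~padded) - 1
    out = np.zeros(vox.shape)
    for idx in np.argwhere(vox):
        d = np.linalg.norm((bg - idx) * sp, axis=1)
        out[tuple(idx)] = d.min()
    return out


class TestDistanceMap:
    @pytest.mark.parametrize("seed,p", [(0, 0.4), (1, 0.7)])
    def test_matches_brute_force_on_small_grids(self, seed, p):
        rng = np.random.default_rng(seed)
        vox = rng.random((4, 8, 8)) < p
        vox[2, 4, 4] = True
        mask = BinaryMask(vox, (0.4, 0.1, 0.1))
        np.testing.assert_allclose(sg.distance_map(mask),
                                   _brute_force_edt(vox, mask.spacing), rtol=1e-12)

    def test_single_voxel(self):
        vox = np.zeros((3, 5, 5), dtype=bool)
        vox[1, 2, 2] = True
        mask = BinaryMask(vox, (0.4, 0.1, 0.1))
        dmap = sg.distance_map(mask)
        assert dmap[1, 2, 2] == pytest.approx(0.1)

    def test_all_foreground_grows_from_faces(self):
        mask = BinaryMask(np.ones((4, 8, 8), bool), (0.2, 0.1, 0.1))
        dmap = sg.distance_map(mask)
        np.testing.assert_allclose(dmap, _brute_force_edt(mask.voxels, mask.spacing),
                                   rtol=1e-12)
        assert dmap[0, 0, 0] < dmap[2, 4, 4]

    def test_solid_cylinder_axis_distance(self):
        r = 0.45
        sp = (0.2, 0.1, 0.1)
        shape = (5, 12, 30)
        zz, yy, _ = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)],
                                indexing="ij")
        vox = ((zz - 0.5) ** 2 + (yy - 0.6) ** 2) <= r ** 2
        mask = BinaryMask(vox, sp)
        dmap = sg.distance_map(mask)
        axis_vals = dmap[2, 6, 5:25]
        assert np.all(np.abs(axis_vals - r) <= max(sp) + 1e-9)


def _extract(graph, spec, config):
    img = render_phantom(graph, spec)
    mask = segment_stack(img, config)
    dmap = sg.distance_map(mask)
    cl = sg.extract_centerline(mask, config.prune_length_um,
                               config.thinning_z_compression)
    return sg.build_graph(cl, dmap, config, image=img), mask


class TestGraphExtraction:
    def test_y_phantom_topology(self, config, clean_spec):
        gr, _ = _extract(y_graph(center=(2.0, 3.0, 3.0)), clean_spec, config)
        kinds = sorted(n.kind for n in gr.nodes)
        assert kinds == ["junction", "open", "open", "open"]
        junction = [n for n in gr.nodes if n.kind == "junction"][0]
        assert junction.degree == 3
        assert len(gr.segments) == 3
        assert gr.n_components == 1 and gr.cycle_rank == 0

    def test_straight_tube_single_segment_and_length(self, config, clean_spec):
        true_len = 4.0
        gr, _ = _extract(tube_graph(length_um=true_len, radius_nm=150.0,
                                    center=(2.0, 3.0, 3.0)), clean_spec, config)
        assert sorted(n.kind for n in gr.nodes) == ["open", "open"]
        assert len(gr.segments) == 1
        assert abs(gr.segments[0].length_um - true_len) <= 2 * 0.042

    def test_tube_thickness_from_distance_map(self, config, clean_spec):
        gr, _ = _extract(tube_graph(length_um=4.0, radius_nm=150.0,
                                    center=(2.0, 3.0, 3.0)), clean_spec, config)
        interior = np.concatenate([s.thickness_nm[3:-3] for s in gr.segments])
        assert abs(interior.mean() - 300.0) <= 42.0

    def test_torus_is_single_closed_loop(self, config, clean_spec):
        gr, _ = _extract(torus_graph(major_radius_um=1.5, center=(2.0, 3.0, 3.0)),
                         clean_spec, config)
        assert len(gr.segments) == 1
        assert gr.nodes[0].kind == "cycle"
        assert gr.cycle_rank == 1
        assert sum(1 for n in gr.nodes if n.kind == "open") == 0
        assert gr.segments[0].length_um == pytest.approx(2 * np.pi * 1.5, rel=0.03)

    def test_segment_length_bounds_euclidean_distance(self, config, clean_spec):
        gr, _ = _extract(y_graph(center=(2.0, 3.0, 3.0)), clean_spec, config)
        for seg in gr.segments:
            a = gr.node_by_id(seg.nodes[0]).position
            b = gr.node_by_id(seg.nodes[1]).position
            assert seg.length_um >= np.linalg.norm(a - b) - 1e-9

    def test_inplane_rotation_invariance(self, config):
        spec = PhantomSpec(seed=3, **CLEAN_RENDER)
        img = render_phantom(y_graph(arm_length_um=1.2, center=(2.0, 3.0, 3.0)), spec)
        mask = segment_stack(img, config)
        rot = BinaryMask(np.rot90(mask.voxels, axes=(1, 2)).copy(), mask.spacing)
        graphs = []
        for m in (mask, rot):
            dmap = sg.distance_map(m)
            cl = sg.extract_centerline(m, config.prune_length_um,
                                       config.thinning_z_compression)
            graphs.append(sg.build_graph(cl, dmap, config))
        g0, g1 = graphs
        assert len(g0.nodes) == len(g1.nodes)
        assert sorted(n.degree for n in g0.nodes) == sorted(n.degree for n in g1.nodes)
        tot0 = sum(s.length_um for s in g0.segments)
        tot1 = sum(s.length_um for s in g1.segments)
        assert tot1 == pytest.approx(tot0, rel=0.02)

    def test_thickness_positive_everywhere(self, config, clean_spec):
        gr, _ = _extract(y_graph(center=(2.0, 3.0, 3.0)), clean_spec, config)
        for seg in gr.segments:
            assert np.all(seg.thickness_nm > 0)
        for n in gr.nodes:
            assert n.thickness_nm > 0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            sg.extract_centerline(BinaryMask(np.zeros((2, 3, 3), bool), (1, 1, 1)))
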