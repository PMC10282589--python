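"""Generator contracts: tree topology, rasterization, rendering, pairing."""

import numpy as np
import pytest

from retvas.morphometrics import vessel_density
from retvas.skeleton import GraphEdge, VesselGraph
from retvas.synthetic import (
    REFERENCE_PROFILE,
    DeviceProfile,
    VesselTree,
    effective_vessel_mask,
    generate_vessel_tree,
    make_paired_dataset,
    rasterize,
    render_float,
    render_fundus,
    score_segmentation,
)

from conftest import make_eye


class TestGenerateVesselTree:
    def test_no_branching_gives_one_edge_per_root(self):
        t = generate_vessel_tree(1, n_roots=3, branch_prob=0.0)
        assert t.n_edges == 3
        assert t.n_terminal == 3
        assert t.n_bifurcation == 0

    def test_full_binary_tree_depth_three(self):
        # 1 + 2 + 4 edges; 4 leaves; 3 internal branch points
        t = generate_vessel_tree(5, n_roots=1, branch_prob=1.0, depth_max=3)
        assert t.n_edges == 7
        assert t.n_terminal == 4
        assert t.n_bifurcation == 3

    def test_same_seed_is_bit_identical(self):
        t1 = generate_vessel_tree(42)
        t2 = generate_vessel_tree(42)
        assert t1.n_edges == t2.n_edges
        for e1, e2 in zip(t1.graph.edges, t2.graph.edges):
            np.testing.assert_array_equal(e1.polyline, e2.polyline)
        assert t1.widths == t2.widths

    def test_child_widths_strictly_taper(self):
        t = generate_vessel_tree(3, n_roots=2, branch_prob=1.0, depth_max=4)
        by_edge = {i: w for i, w in enumerate(t.widths)}
        parent_of = {}
        for i, e in enumerate(t.graph.edges):
            for j, e2 in enumerate(t.graph.edges):
                if i != j and e2.a == e.b:
                    parent_of[j] = i
        assert parent_of  # tree actually branched
        for child, parent in parent_of.items():
            assert by_edge[child] < by_edge[parent]

    def test_coordinates_inside_fov(self):
        t = generate_vessel_tree(9, depth_max=8)
        cr, cc = t.fov_centre
        for e in t.graph.edges:
            d = np.hypot(e.polyline[:, 0] - cr, e.polyline[:, 1] - cc)
            assert (d <= t.fov_radius).all()

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_roots=0), dict(branch_prob=1.5), dict(branch_prob=-0.1),
         dict(width_root_px=0.5), dict(fov_radius=-1)],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            generate_vessel_tree(0, **kwargs)


class TestRasterize:
    def test_empty_graph_rasterizes_to_zero_density(self):
        tree = VesselTree(
            graph=VesselGraph(), widths=[], fov_centre=(64, 64), fov_radius=60,
            od_centre=(64, 90), od_radius=8,
        )
        gt = rasterize(tree, (128, 128))
        assert not gt.vessel_mask.any()
        assert gt.true_density == 0.0

    def test_single_stroke_pixel_count(self):
        # 100-px horizontal segment, width 5, far from the FOV edge:
        # the stroked area is 500 px up to end-cap rounding
        g = VesselGraph()
        g.edges.append(GraphEdge(a=0, b=1, polyline=np.array([[200.0, 150.0], [200.0, 250.0]]), length=100))
        tree = VesselTree(graph=g, widths=[5.0], fov_centre=(200, 200), fov_radius=190,
                          od_centre=(200, 300), od_radius=10)
        gt = rasterize(tree, (400, 400))
        assert 480 <= gt.vessel_mask.sum() <= 520

    def test_mask_subset_of_fov_and_density_consistent(self):
        gt = rasterize(generate_vessel_tree(4))
        assert not (gt.vessel_mask & ~gt.fov_mask).any()
        expect = 100.0 * (gt.vessel_mask & gt.fov_mask).sum() / gt.fov_mask.sum()
        assert gt.true_density == pytest.approx(expect, abs=1e-12)

    def test_graph_outside_raster_raises_with_segment_id(self):
        g = VesselGraph()
        g.edges.append(GraphEdge(a=0, b=1, polyline=np.array([[10.0, -5.0], [10.0, 20.0]]), length=25))
        tree = VesselTree(graph=g, widths=[3.0], fov_centre=(32, 32), fov_radius=30,
                          od_centre=(32, 40), od_radius=4)
        with pytest.raises(ValueError, match="segment 0"):
            rasterize(tree, (64, 64))

    def test_density_monotone_in_root_width(self):
        # thicker vessels must fill more of the FOV, seed by seed
        for seed in range(20):
            dens = [
                rasterize(generate_vessel_tree(seed, width_root_px=w, fov_radius=184,
                                               fov_centre=(192, 192), od_radius=20,
                                               root_len=58), (384, 384)).true_density
                for w in (4.0, 6.0, 8.0)
            ]
            assert dens[0] < dens[1] < dens[2]


class TestRenderFundus:
    def test_vessel_contrast_is_exact_in_green(self):
        _, gt, img = make_eye(2, size=384)
        blank = rasterize(
            VesselTree(graph=VesselGraph(), widths=[], fov_centre=gt.tree.fov_centre,
                       fov_radius=gt.tree.fov_radius, od_centre=gt.od_centre,
                       od_radius=gt.od_radius),
            gt.fov_mask.shape,
        )
        blank.tree = gt.tree
        clean = render_fundus(blank, REFERENCE_PROFILE, 2)
        diff = clean.pixels[..., 1].astype(int) - img.pixels[..., 1].astype(int)
        v = gt.vessel_mask
        assert (diff[v] == 60).all()  # configured vessel depth, exactly
        assert (diff[~v] == 0).all()

    def test_erosion_strictly_shrinks_rendered_vessels(self):
        _, gt, _ = make_eye(2, size=384)
        prof = DeviceProfile("e", vessel_erosion_px=1)
        assert effective_vessel_mask(gt, prof).sum() < gt.vessel_mask.sum()
        assert (effective_vessel_mask(gt, prof) & ~gt.vessel_mask).sum() == 0

    def test_brightness_gain_scales_mean_green(self):
        _, gt, _ = make_eye(3, size=384)
        ref = render_float(gt, REFERENCE_PROFILE, 0)
        dim = render_float(gt, DeviceProfile("dim", brightness_gain=0.6), 0)
        fov = gt.fov_mask
        ratio = dim[..., 1][fov].mean() / ref[..., 1][fov].mean()
        assert ratio == pytest.approx(0.6, rel=1e-12)

    def test_vessels_darker_than_background_in_green(self):
        _, gt, img = make_eye(4, size=384)
        g = img.pixels[..., 1].astype(float)
        v = gt.vessel_mask
        bg = gt.fov_mask & ~gt.vessel_mask
        assert g[v].mean() < g[bg].mean() - 20

    def test_contrast_monotone_in_degradation(self):
        # green vessel/background contrast falls as contrast_gain drops
        # and as blur grows
        _, gt, _ = make_eye(5, size=384)
        v = gt.vessel_mask
        b = gt.fov_mask & ~gt.vessel_mask

        def contrast(profile):
            px = render_fundus(gt, profile, 0).pixels[..., 1].astype(float)
            return px[b].mean() - px[v].mean()

        by_gain = [contrast(DeviceProfile("c", contrast_gain=g)) for g in (1.0, 0.8, 0.6, 0.4)]
        assert all(a > b_ for a, b_ in zip(by_gain, by_gain[1:]))
        by_blur = [contrast(DeviceProfile("b", blur_sigma=s)) for s in (0.0, 1.0, 2.0, 3.0)]
        assert all(a > b_ for a, b_ in zip(by_blur, by_blur[1:]))

    def test_noise_is_seed_deterministic(self):
        _, gt, _ = make_eye(6, size=256)
        prof = DeviceProfile("n", noise_sd=5.0)
        a = render_fundus(gt, prof, 123).pixels
        b = render_fundus(gt, prof, 123).pixels
        np.testing.assert_array_equal(a, b)


class TestMakePairedDataset:
    def test_pair_count_matches_request(self):
        pairs = make_paired_dataset(56, seed=0, image_size=(256, 256))
        assert len(pairs) == 56

    def test_identical_profiles_render_identically(self):
        pairs = make_paired_dataset(2, hh_profile=REFERENCE_PROFILE, seed=5,
                                    image_size=(256, 256))
        for ref, hh, _ in pairs:
            np.testing.assert_array_equal(ref.pixels, hh.pixels)

    def test_fixed_seed_reproduces_dataset(self):
        a = make_paired_dataset(3, seed=9, image_size=(256, 256), hh_jitter=0.25)
        b = make_paired_dataset(3, seed=9, image_size=(256, 256), hh_jitter=0.25)
        for (r1, h1, g1), (r2, h2, g2) in zip(a, b):
            np.testing.assert_array_equal(r1.pixels, r2.pixels)
            np.testing.assert_array_equal(h1.pixels, h2.pixels)
            np.testing.assert_array_equal(g1.vessel_mask, g2.vessel_mask)

    def test_known_bias_is_exact_mask_arithmetic(self):
        # an erosion-only handheld arm has a density deficit computable
        # exactly from the two masks
        prof = DeviceProfile("thin", vessel_erosion_px=1)
        pairs = make_paired_dataset(2, hh_profile=prof, seed=1, image_size=(384, 384))
        for _, _, gt in pairs:
            thin = effective_vessel_mask(gt, prof)
            delta = gt.true_density - vessel_density(thin, gt.fov_mask)
            assert delta > 0.5  # a 1-px erosion visibly thins 2-9 px vessels


class TestScoreSegmentation:
    def _fov(self):
        fov = np.zeros((32, 32), bool)
        fov[4:28, 4:28] = True
        return fov

    def test_perfect_prediction(self):
        fov = self._fov()
        truth = np.zeros_like(fov)
        truth[10:14, 6:20] = True
        s = score_segmentation(truth, truth, fov)
        assert s.tpr == 1.0 and s.fpr == 0.0

    def test_empty_prediction(self):
        fov = self._fov()
        truth = np.zeros_like(fov)
        truth[10:14, 6:20] = True
        s = score_segmentation(np.zeros_like(fov), truth, fov)
        assert s.tpr == 0.0 and s.fpr == 0.0

    def test_complement_prediction(self):
        fov = self._fov()
        truth = np.zeros_like(fov)
        truth[10:14, 6:20] = True
        s = score_segmentation(fov & ~truth, truth, fov)
        assert s.tpr == 0.0 and s.fpr == 1.0

    def test_empty_truth_raises(self):
        fov = self._fov()
        with pytest.raises(ValueError, match="TPR undefined"):
            score_segmentation(np.zeros_like(fov), np.zeros_like(fov), fov)
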