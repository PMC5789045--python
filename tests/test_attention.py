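"""Gradient-weighted attention maps: closed forms, oracles and rendering."""

import numpy as np
import pytest

from kneekl.attention import (AttentionPair, branch_cam, ensemble_cam,
                              render_overlay)
from kneekl.ensemble import EnsembleBundle
from kneekl.model import BranchSpec, build
from kneekl.patches import PatchGeometry, PatchPair


def _pair(size, seed=0):
    rng = np.random.default_rng(seed)
    geom = PatchGeometry(resized_px=size, S=size, K=0,
                         lateral_origin=(0, 0), medial_origin=(0, 0))
    return PatchPair(rng.uniform(0, 255, (size, size)),
                     rng.uniform(0, 255, (size, size)), geom)


def spatial_average_gradient_cam(net, patch, head_row_half):
    """Oracle: explicit per-pixel gradient of the class score, averaged.

    Chain rule written out by hand in float64: through the head the gradient
    at pooled feature k is the weight-row entry, and through global average
    pooling every pixel of map k receives that value divided by X*Y.  The
    per-pixel gradients are laid out as a full field and then spatially
    averaged — the classic two-step formulation.
    """
    acts, _ = net.branch_features(patch)
    acts = acts.astype(np.float64)
    C, X, Y = acts.shape
    grad_field = np.empty((C, X, Y))
    for k in range(C):
        grad_field[k] = head_row_half[k] / (X * Y)
    weights = grad_field.mean(axis=(1, 2))  # spatially averaged gradient
    return np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)


class TestBranchCam:
    def test_zero_head_block_gives_zero_map(self, tiny_spec):
        net = build(tiny_spec, input_px=40, seed=0)
        half = net.descriptor_dim // 2
        net.head.W.value[:, :half] = 0.0
        cam = branch_cam(net, _pair(40, seed=1), c=2)
        assert (cam.lateral_map == 0).all()
        assert (cam.medial_map >= 0).all()

    def test_closed_form_on_two_channel_toy(self):
        # widths ending in 2 at a 40-px input give 2-channel 2x2 maps;
        # with a hand-set head row the map is ReLU(w0*A0 + w1*A1)
        spec = BranchSpec(widths=(1, 1, 2, 2, 2), pool_after=frozenset({2}))
        net = build(spec, dropout=0.0, input_px=40, seed=3)
        net.head.W.value[:] = 0.0
        net.head.W.value[1, 0], net.head.W.value[1, 1] = 2.0, -1.0  # lateral half
        pair = _pair(40, seed=4)
        acts, _ = net.branch_features(pair.lateral)
        expected = np.maximum(2.0 * acts[0] - 1.0 * acts[1], 0.0)
        cam = branch_cam(net, pair, c=1)
        np.testing.assert_allclose(cam.lateral_map, expected, rtol=1e-6, atol=1e-7)
        assert (cam.medial_map == 0).all()

    def test_matches_spatial_average_gradient_oracle(self, tiny_spec):
        for seed in range(5):
            net = build(tiny_spec, input_px=40, seed=seed)
            pair = _pair(40, seed=100 + seed)
            c = seed % 5
            cam = branch_cam(net, pair, c)
            half = net.descriptor_dim // 2
            row = net.head.W.value[c].astype(np.float64)
            for ref_map, patch, row_half in (
                (cam.lateral_map, pair.lateral, row[:half]),
                (cam.medial_map, pair.medial, row[half:]),
            ):
                oracle = spatial_average_gradient_cam(net, patch, row_half)
                # equal up to the positive scale 1/(XY)
                scale = ref_map.size
                np.testing.assert_allclose(oracle * scale, ref_map,
                                           rtol=1e-5, atol=1e-8)

    def test_finite_difference_anchor(self, tiny_spec):
        """Weights equal true pooled-feature gradients (loose float32 tol)."""
        net = build(tiny_spec, input_px=40, seed=9)
        pair = _pair(40, seed=9)
        c = 3
        _, pl = net.branch_features(pair.lateral)
        _, pm = net.branch_features(pair.medial)
        half = net.descriptor_dim // 2
        row = net.head.W.value[c]
        eps = 1e-2
        for k in range(half):
            plp, plm = pl.copy(), pl.copy()
            plp[k] += eps
            plm[k] -= eps
            sp, _ = net.head.forward(np.concatenate([plp, pm])[None].astype(np.float32))
            sm, _ = net.head.forward(np.concatenate([plm, pm])[None].astype(np.float32))
            fd = (sp[0, c] - sm[0, c]) / (2 * eps)
            assert fd == pytest.approx(row[k], rel=1e-2, abs=1e-4)

    def test_invalid_class_rejected(self, tiny_net, tiny_pair):
        with pytest.raises(ValueError):
            branch_cam(tiny_net, tiny_pair, c=5)


class TestEnsembleCam:
    def test_single_member_equals_branch_cam(self, tiny_spec, tiny_pair):
        net = build(tiny_spec, input_px=40, seed=0)
        single = branch_cam(net, tiny_pair, 2)
        fused = ensemble_cam(EnsembleBundle([net], seeds=[0]), tiny_pair, 2)
        np.testing.assert_array_equal(single.lateral_map, fused.lateral_map)
        np.testing.assert_array_equal(single.medial_map, fused.medial_map)

    def test_identical_members_triple_the_map(self, tiny_spec, tiny_pair):
        net = build(tiny_spec, input_px=40, seed=1)
        bundle = EnsembleBundle([net, net, net], seeds=[1, 1, 1])
        fused = ensemble_cam(bundle, tiny_pair, 0)
        single = branch_cam(net, tiny_pair, 0)
        np.testing.assert_allclose(fused.lateral_map, 3 * single.lateral_map,
                                   rtol=1e-12)

    def test_mixed_map_sizes_rejected(self, tiny_spec, tiny_pair):
        a = build(tiny_spec, input_px=40, seed=0)
        # same widths but no pooling: 11x11 maps instead of 2x2
        b = build(BranchSpec(widths=tiny_spec.widths, pool_after=frozenset()),
                  input_px=40, seed=0)
        bundle = EnsembleBundle([a], seeds=[0])
        bundle.members.append(b)  # bypasses the constructor's spec check
        with pytest.raises(ValueError, match="mixed"):
            ensemble_cam(bundle, tiny_pair, 0)


class TestRenderOverlay:
    def _maps(self, lat, med, geom):
        return AttentionPair(lat, med, 0, geom)

    def test_zero_maps_give_zero_overlay(self, default_geom):
        ov = render_overlay(self._maps(np.zeros((10, 10)), np.zeros((10, 10)),
                                       default_geom))
        assert (ov.heatmap == 0).all()

    def test_lateral_hotspot_lands_top_left_of_lateral_patch(self, default_geom):
        lat = np.zeros((10, 10))
        lat[0, 0] = 5.0
        ov = render_overlay(self._maps(lat, np.zeros((10, 10)), default_geom))
        assert ov.heatmap.max() == 1.0
        y, x = np.unravel_index(ov.heatmap.argmax(), ov.heatmap.shape)
        assert x < 15 and 100 <= y < 115  # top-left corner of the lateral patch

    def test_medial_hotspot_unflips_to_right_edge(self, default_geom):
        med = np.zeros((10, 10))
        med[0, 0] = 1.0
        ov = render_overlay(self._maps(np.zeros((10, 10)), med, default_geom))
        y, x = np.unravel_index(ov.heatmap.argmax(), ov.heatmap.shape)
        assert x > 285 and 100 <= y < 115

    def test_range_is_zero_to_one(self, default_geom):
        rng = np.random.default_rng(5)
        ov = render_overlay(self._maps(rng.uniform(0, 3, (10, 10)),
                                       rng.uniform(0, 3, (10, 10)), default_geom))
        assert ov.heatmap.min() == 0.0
        assert ov.heatmap.max() == 1.0

    def test_negative_maps_rejected(self, default_geom):
        with pytest.raises(ValueError):
            self._maps(-np.ones((10, 10)), np.zeros((10, 10)), default_geom)
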