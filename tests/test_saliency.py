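"""Saliency CNN architecture, map construction, binarization, localization."""

import numpy as np
import pytest

from endoml import _nn
from endoml.saliency import (SaliencyCNNSpec, SaliencyTrainConfig, binarize,
                             build_network, build_saliency_cnn,
                             compute_saliency_map, localize, morph_refine,
                             refine_map, train_saliency_cnn)
from endoml.synthdata import FrameRecipe, make_frames


class TestArchitecture:
    def test_fourteen_layers(self):
        spec = build_saliency_cnn((256, 256, 3), 8)
        assert spec.layer_count == 14

    def test_layer_inventory(self):
        spec = build_saliency_cnn((64, 64, 3), 2)
        inv = spec.inventory()
        assert inv == {"conv": 3, "maxpool": 2, "batchnorm": 3, "relu": 3,
                       "avgpool": 1, "fc": 1, "softmax": 1}
        assert sum(inv.values()) == 14

    def test_network_materializes_spec_order(self):
        spec = build_saliency_cnn((64, 64, 3), 2)
        net = build_network(spec, seed=0)
        convs = [l for l in net.layers if isinstance(l, _nn.Conv2D)]
        assert len(convs) == 3
        assert all(c.stride == 2 and c.k == 3 for c in convs)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            build_saliency_cnn((64, 64, 3), 1)
        with pytest.raises(ValueError):
            build_saliency_cnn((50, 50, 3), 2)


class TestTraining:
    def test_learns_separable_fixture(self, small_frames):
        images, _, labels = small_frames
        cfg = SaliencyTrainConfig(epochs=60, seed=0)
        net = train_saliency_cnn(images, labels, cfg)
        acc = (net.predict(images.transpose(0, 3, 1, 2)) == labels).mean()
        assert acc > 0.9

    def test_same_seed_identical_weights(self, small_frames):
        images, _, labels = small_frames
        cfg = SaliencyTrainConfig(epochs=3, seed=4)
        nets = [train_saliency_cnn(images[:8], labels[:8], cfg) for _ in range(2)]
        for a, b in zip(nets[0].params(), nets[1].params()):
            assert np.array_equal(a, b)

    def test_single_class_rejected(self, small_frames):
        images, _, _ = small_frames
        with pytest.raises(ValueError):
            train_saliency_cnn(images[:4], np.zeros(4, dtype=int))


class TestSaliencyMap:
    def test_constant_image_gives_zero_map(self, trained_segmenter):
        out = compute_saliency_map(trained_segmenter.network_,
                                   np.full((96, 96, 3), 0.5))
        assert np.allclose(out, 0.0)

    def test_top_k_all_equals_mean_of_folded_maps(self, trained_segmenter,
                                                  small_frames):
        images, _, _ = small_frames
        net = trained_segmenter.network_
        full = compute_saliency_map(net, images[0], top_k=16)
        # oracle: forward to conv2 by hand, fold, average all maps
        x = images[0].transpose(2, 0, 1)[None]
        h, seen = x, 0
        for layer in net.layers:
            h = layer.forward(h, train=False)
            if isinstance(layer, _nn.Conv2D):
                seen += 1
                if seen == 2:
                    break
        maps = h[0]

        def norm01(a):
            lo, hi = a.min(), a.max()
            return np.zeros_like(a) if hi - lo < 1e-12 else (a - lo) / (hi - lo)

        folded = np.stack([norm01(np.abs(m - np.median(m))) for m in maps])
        from skimage.transform import resize
        up = resize(folded.mean(axis=0), images[0].shape[:2], order=1,
                    mode="reflect", anti_aliasing=False, preserve_range=True)
        assert np.allclose(full, norm01(up))

    def test_excess_top_k_clipped_with_warning(self, trained_segmenter,
                                               small_frames):
        images, _, _ = small_frames
        with pytest.warns(UserWarning):
            out = compute_saliency_map(trained_segmenter.network_, images[0],
                                       top_k=999)
        assert out.shape == images[0].shape[:2]

    def test_map_in_unit_range(self, trained_segmenter, small_frames):
        images, _, _ = small_frames
        out = compute_saliency_map(trained_segmenter.network_, images[1])
        assert out.min() >= 0 and out.max() <= 1

    def test_map_highlights_lesion_across_seeds(self):
        """Trained maps should rank the lesion above the background."""
        hits = 0
        for seed in range(10):
            images, masks, labels = make_frames(
                FrameRecipe(n_frames=12, seed=seed))
            cfg = SaliencyTrainConfig(epochs=60, seed=seed)
            net = train_saliency_cnn(images, labels, cfg)
            m = compute_saliency_map(net, images[0])
            hits += m[masks[0]].mean() > m[~masks[0]].mean()
        assert hits >= 8


class TestRefineBinarize:
    def test_zero_enhancement_is_identity_modulo_norm(self, rng):
        omap = rng.random((8, 8))
        out = refine_map(omap, np.zeros((8, 8, 3)))
        expect = (omap - omap.min()) / (omap.max() - omap.min())
        assert np.allclose(out, expect)

    def test_zero_map_returns_normalized_channel_mean(self, rng):
        enh = rng.random((8, 8, 3))
        out = refine_map(np.zeros((8, 8)), enh)
        cm = enh.mean(axis=2)
        assert np.allclose(out, (cm - cm.min()) / (cm.max() - cm.min()))

    def test_matches_elementwise_oracle(self, rng):
        omap = rng.random((4, 4))
        enh = rng.random((4, 4, 3))
        out = refine_map(omap, enh)
        raw = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                raw[i, j] = omap[i, j] + sum(enh[i, j]) / 3.0
        expect = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(out, expect)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            refine_map(np.zeros((4, 4)), np.zeros((5, 5, 3)))

    def test_binarize_printed_example(self):
        out = binarize(np.array([[0.2, 0.4], [0.6, 0.8]]))
        assert np.array_equal(out, [[0, 0], [1, 1]])

    def test_binarize_constant_map_all_foreground(self):
        assert binarize(np.full((3, 3), 0.7)).all()

    def test_binarize_matches_threshold_oracle(self, rng):
        m = rng.random((16, 16))
        out = binarize(m)
        assert np.array_equal(out.astype(bool), m >= m.mean())
        assert out.sum() == np.count_nonzero(m >= m.mean())
        assert set(np.unique(out)) <= {0, 1}


class TestMorphLocalize:
    def test_interior_hole_filled(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = 1
        mask[9:11, 9:11] = 0
        out = morph_refine(mask, radius=1)
        assert out[9:11, 9:11].all()

    def test_one_pixel_gap_closed(self):
        mask = np.zeros((10, 20), dtype=np.uint8)
        mask[4:7, 2:9] = 1
        mask[4:7, 10:17] = 1
        out = morph_refine(mask, radius=2)
        assert out[5, 9] == 1

    def test_empty_stays_empty_and_never_shrinks(self, rng):
        assert morph_refine(np.zeros((8, 8), dtype=np.uint8), 2).sum() == 0
        mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        out = morph_refine(mask, 2)
        assert (out >= mask).all()

    def test_empty_mask_yields_no_regions(self, rng):
        assert localize(np.zeros((32, 32)), rng.random((32, 32, 3))) == []

    def test_solid_square_box_and_area(self):
        mask = np.zeros((96, 96), dtype=np.uint8)
        mask[20:60, 30:70] = 1
        img = np.full((96, 96, 3), 0.7)
        img[20:60, 30:70] = 0.2
        regions = localize(mask, img, min_area=64)
        assert len(regions) == 1
        r0, c0, r1, c1 = regions[0].box
        assert r0 <= 20 and c0 <= 30 and r1 >= 60 and c1 >= 70
        assert abs(regions[0].area - 1600) <= 0.2 * 1600

    def test_two_blobs_sorted_by_area(self):
        mask = np.zeros((96, 96), dtype=np.uint8)
        mask[10:30, 10:30] = 1     # area 400
        mask[50:80, 50:80] = 1     # area 900
        img = np.full((96, 96, 3), 0.8)
        img[mask.astype(bool)] = 0.2
        regions = localize(mask, img, min_area=64)
        assert len(regions) == 2
        assert regions[0].area >= regions[1].area
        assert regions[0].box[0] >= 40  # the big blob leads
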