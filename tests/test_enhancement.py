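"""Contrast-enhancement chain: stage oracles and whole-chain invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from endoml.enhancement import (ContrastEnhancer, EnhancementConfig, dehaze,
                                denoise_channels, enhance, fuse_final,
                                fuse_hat, split_channels, top_bottom_hat)
from endoml.synthdata import FrameRecipe, make_frames

images_8x8 = arrays(float, (8, 8, 3),
                    elements=st.floats(0, 1, allow_nan=False, width=32))


def michelson(gray, mask):
    a, b = gray[mask].mean(), gray[~mask].mean()
    return abs(a - b) / (a + b + 1e-9)


class TestSplitChannels:
    def test_pure_red_splits_to_indicator_planes(self):
        img = np.zeros((4, 4, 3))
        img[:, :, 0] = 1.0
        c1, c2, c3 = split_channels(img)
        assert (c1 == 1).all() and (c2 == 0).all() and (c3 == 0).all()

    def test_round_trip_recombination(self, rng):
        img = rng.random((6, 5, 3))
        assert np.array_equal(np.stack(split_channels(img), axis=2), img)

    def test_known_2x2_values_read_directly(self):
        img = np.arange(12).reshape(2, 2, 3) / 12.0
        c1, c2, c3 = split_channels(img)
        assert c1[0, 1] == 3 / 12 and c2[1, 0] == 7 / 12 and c3[1, 1] == 11 / 12

    def test_rejects_non_three_channel(self):
        with pytest.raises(ValueError):
            split_channels(np.zeros((4, 4)))


class TestDenoise:
    def test_identity_denoiser_returns_input(self, rng):
        img = rng.random((5, 5, 3))
        _, f4 = denoise_channels(split_channels(img), "identity")
        assert np.array_equal(f4, img)

    def test_median_leaves_constant_plane(self):
        planes = (np.full((6, 6), 0.4),) * 3
        (f1, _, _), _ = denoise_channels(planes, "median")
        assert np.allclose(f1, 0.4)

    def test_median_removes_salt_pixel_matching_bruteforce(self, rng):
        plane = rng.random((7, 7)) * 0.1
        plane[3, 3] = 1.0
        (f1, _, _), _ = denoise_channels((plane,) * 3, "median")
        padded = np.pad(plane, 1, mode="symmetric")
        expect = np.empty_like(plane)
        for i in range(7):
            for j in range(7):
                expect[i, j] = np.median(padded[i:i + 3, j:j + 3])
        assert np.allclose(f1, expect)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            denoise_channels((np.zeros((3, 3)), np.zeros((3, 3)),
                              np.zeros((4, 4))), "median")


class TestHats:
    def test_constant_image_gives_zero_hats(self):
        img = np.full((16, 16, 3), 0.6)
        top, bot = top_bottom_hat(img, 3)
        assert np.allclose(top, 0) and np.allclose(bot, 0)

    def test_isolated_peak_survives_tophat(self):
        img = np.zeros((7, 7, 3))
        img[3, 3, :] = 1.0
        top, _ = top_bottom_hat(img, 2)
        assert top[3, 3, 0] == pytest.approx(1.0)
        assert np.count_nonzero(top[:, :, 0]) == 1

    def test_duality_tophat_of_inverse_is_bothat(self, rng):
        img = rng.random((8, 8, 3))
        top_inv, _ = top_bottom_hat(1.0 - img, 2)
        _, bot = top_bottom_hat(img, 2)
        assert np.allclose(top_inv, bot, atol=1e-12)

    def test_hats_nonnegative_on_random_images(self, rng):
        for _ in range(5):
            top, bot = top_bottom_hat(rng.random((10, 10, 3)), 2)
            assert top.min() >= 0 and bot.min() >= 0

    def test_oversized_selem_rejected(self):
        with pytest.raises(ValueError):
            top_bottom_hat(np.zeros((8, 8, 3)), 4)


class TestFusions:
    def test_constant_image_clamps_to_zero(self):
        c = np.full((4, 4, 3), 0.3)
        out = fuse_hat(np.zeros_like(c), np.zeros_like(c), c)
        assert np.allclose(out, 0.0)

    def test_halves_arithmetic(self):
        shape = (2, 2, 3)
        out = fuse_hat(np.full(shape, 0.5), np.full(shape, 0.5),
                       np.full(shape, 0.3))
        assert np.allclose(out, 0.7)

    def test_fuse_hat_matches_scalar_loop(self, rng):
        top, bot, orig = (rng.random((4, 4, 3)) for _ in range(3))
        out = fuse_hat(top, bot, orig)
        for idx in np.ndindex(4, 4, 3):
            assert out[idx] == pytest.approx(
                min(max(top[idx] + bot[idx] - orig[idx], 0.0), 1.0))

    def test_fuse_final_annihilated_by_zero_tophat(self, rng):
        hz = rng.random((4, 4, 3))
        out = fuse_final(hz, rng.random((4, 4, 3)), np.zeros((4, 4, 3)))
        assert np.allclose(out, np.clip(hz, 0, 1))

    def test_fuse_final_all_ones_saturates(self):
        ones = np.ones((3, 3, 3))
        assert np.allclose(fuse_final(ones, ones, ones), 1.0)

    def test_fuse_final_matches_scalar_loop(self, rng):
        hz, fz, tp = (rng.random((4, 4, 3)) for _ in range(3))
        out = fuse_final(hz, fz, tp)
        for idx in np.ndindex(4, 4, 3):
            assert out[idx] == pytest.approx(
                min(hz[idx] * (fz[idx] * tp[idx]) + hz[idx], 1.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_hat(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)),
                     np.zeros((4, 4, 3)))


class TestDehaze:
    def test_haze_free_image_nearly_unchanged(self, rng):
        img = rng.random((32, 32, 3))
        img[:, :, 2] = 0.0  # dark channel identically zero
        out = dehaze(img)
        assert np.abs(out - img).max() < 0.05

    def test_recovers_synthetically_veiled_scene(self, rng):
        scene = rng.random((32, 32, 3))
        scene[:, :, 2] *= 0.05
        veiled = 0.5 * scene + 0.5
        out = dehaze(veiled)
        rmse = lambda a: np.sqrt(((a - scene) ** 2).mean())
        assert rmse(out) < rmse(veiled)

    def test_constant_white_stays_valid(self):
        out = dehaze(np.ones((20, 20, 3)))
        assert np.isfinite(out).all() and out.min() >= 0 and out.max() <= 1


class TestEnhanceChain:
    def test_deterministic(self, rng):
        img = rng.random((32, 32, 3))
        cfg = EnhancementConfig()
        assert np.array_equal(enhance(img, cfg), enhance(img, cfg))

    def test_black_image_stays_black(self):
        assert np.allclose(enhance(np.zeros((32, 32, 3))), 0.0)

    def test_lesion_contrast_not_decreased(self):
        wins = 0
        for seed in range(10):
            images, masks, _ = make_frames(
                FrameRecipe(n_frames=1, seed=seed, haze=0.0))
            out = enhance(images[0])
            before = michelson(images[0].mean(axis=2), masks[0])
            after = michelson(out.mean(axis=2), masks[0])
            wins += after >= before - 1e-9
        assert wins >= 8

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(images_8x8)
    def test_shape_range_and_finiteness(self, img):
        out = enhance(np.asarray(img, dtype=float), EnhancementConfig(selem_radius=2))
        assert out.shape == img.shape
        assert np.isfinite(out).all() and out.min() >= 0 and out.max() <= 1

    def test_transformer_stacks_frames(self, rng):
        stack = rng.random((2, 32, 32, 3))
        out = ContrastEnhancer().fit(stack).transform(stack)
        assert out.shape == stack.shape

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            EnhancementConfig(denoiser="wavelet")
        with pytest.raises(ValueError):
            EnhancementConfig(dehaze_patch=4)
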