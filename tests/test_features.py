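"""Handcrafted feature extraction: CIELAB stats, GLCM, LBP, LPQ, Gabor."""

import numpy as np
import pytest

import oracles
from woundkit.errors import InvalidInputError
from woundkit.features import (
    FeatureConfig,
    GlcmConfig,
    cielab_distribution_features,
    extract_feature_vector,
    gabor_features,
    glcm,
    glcm_features_full,
    glcm_patch_distribution,
    lbp_histogram,
    lpq_histogram,
    quantize_gray,
    read_features_csv,
    write_features_csv,
)


class TestCielabDistribution:
    def test_constant_patch(self):
        patch = np.full((16, 16, 3), 120.0)
        v = cielab_distribution_features(patch)
        for c in range(3):
            seg = v[20 * c:20 * (c + 1)]
            assert seg[1] == 0.0  # std
            assert seg[2] == 0.0 and seg[3] == 0.0  # skew/kurtosis guard
            hist = seg[4:]
            assert hist.max() == 1.0 and hist.sum() == pytest.approx(1.0)

    def test_histograms_normalized(self, rng):
        v = cielab_distribution_features(rng.integers(0, 255, (32, 32, 3)).astype(float))
        for c in range(3):
            assert v[20 * c + 4:20 * (c + 1)].sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_tone_lightness_histogram(self):
        patch = np.zeros((16, 16, 3))
        patch[:8] = 255.0  # white -> L*=100 (top bin); black excluded? no: black IS bg
        patch[8:] = 60.0   # mid gray
        v = cielab_distribution_features(patch)
        l_hist = v[4:20]
        assert sorted(l_hist[l_hist > 0].tolist()) == [pytest.approx(0.5), pytest.approx(0.5)]

    def test_black_border_invariance(self, rng):
        patch = rng.integers(40, 255, (24, 24, 3)).astype(float)
        bordered = np.zeros((40, 40, 3))
        bordered[8:32, 8:32] = patch
        np.testing.assert_allclose(
            cielab_distribution_features(patch),
            cielab_distribution_features(bordered), atol=1e-9,
        )

    def test_small_patch_rejected(self):
        with pytest.raises(InvalidInputError):
            cielab_distribution_features(np.zeros((4, 4, 3)))


class TestGlcm:
    cfg = GlcmConfig(levels=4, distances=(1,), angles=(0.0,))

    def test_constant_image_all_mass_on_diagonal(self):
        p = glcm(np.zeros((8, 8), dtype=np.uint8), self.cfg)
        assert p[0, 0, 0, 0] == 1.0

    def test_vertical_stripes_all_off_diagonal(self):
        img = np.tile(np.array([0, 1], dtype=np.uint8), (8, 4))
        p = glcm(img, self.cfg)[:, :, 0, 0]
        assert p[0, 0] == 0.0 and p[1, 1] == 0.0
        assert p[0, 1] == pytest.approx(0.5) and p[1, 0] == pytest.approx(0.5)

    def test_matches_pair_enumeration_oracle(self, rng):
        # all four angles and two distances on random small integer images
        # co-occurrence offsets per angle (symmetric, so sign is immaterial)
        offsets = {0.0: (0, 1), 45.0: (1, 1), 90.0: (1, 0), 135.0: (1, -1)}
        cfg = GlcmConfig(levels=5, distances=(1, 2), angles=tuple(offsets))
        for _ in range(100):
            h, w = rng.integers(4, 17, 2)
            img = rng.integers(0, 5, (h, w)).astype(np.uint8)
            p = glcm(img, cfg)
            for di, d in enumerate(cfg.distances):
                for ai, ang in enumerate(cfg.angles):
                    dy, dx = offsets[ang]
                    ref = oracles.glcm_pair_counts(img, 5, dy * d, dx * d)
                    np.testing.assert_allclose(p[:, :, di, ai], ref, atol=1e-12)

    def test_each_slice_normalized(self, rng):
        img = rng.integers(0, 32, (20, 20)).astype(np.uint8)
        p = glcm(img, GlcmConfig())
        np.testing.assert_allclose(p.sum(axis=(0, 1)), 1.0, atol=1e-12)


class TestGlcmFeatures:
    def test_constant_image_feature_values(self):
        v = glcm_features_full(np.full((32, 32), 0.5), GlcmConfig(levels=8))
        # distance-major, property order: contrast, correlation, energy,
        # homogeneity, entropy, dissimilarity
        for d in range(2):
            seg = v[6 * d:6 * (d + 1)]
            assert seg[0] == 0.0          # contrast
            assert seg[2] == pytest.approx(1.0)  # energy
            assert seg[3] == pytest.approx(1.0)  # homogeneity
            assert seg[4] == pytest.approx(0.0)  # entropy
            assert seg[5] == 0.0          # dissimilarity

    def test_checkerboard_contrast_one(self):
        img = np.indices((16, 16)).sum(axis=0) % 2
        cfg = GlcmConfig(levels=2, distances=(1,), angles=(0.0,))
        v = glcm_features_full(img.astype(np.uint8), cfg)
        assert v[0] == pytest.approx(1.0)  # contrast of perfectly alternating levels

    def test_energy_homogeneity_bounds(self, rng):
        v = glcm_features_full(rng.random((40, 40)), GlcmConfig())
        for d in range(2):
            assert 0.0 < v[6 * d + 2] <= 1.0
            assert 0.0 < v[6 * d + 3] <= 1.0


class TestGlcmPatchDistribution:
    def test_tiling_count_128(self, rng):
        # 128x128 -> exactly 4 tiles; verify via a property with zero spread
        img = np.tile(rng.random((64, 64)), (2, 2))
        v = glcm_patch_distribution(img, GlcmConfig())
        stds = v[1::5]
        np.testing.assert_allclose(stds, 0.0, atol=1e-12)  # 4 identical tiles

    def test_smooth_vs_noisy_halves(self, rng):
        img = np.zeros((64, 128))
        img[:, 64:] = rng.random((64, 64))
        v = glcm_patch_distribution(img, GlcmConfig())
        contrast_min, contrast_max = v[2], v[3]
        assert contrast_max > 10 * max(contrast_min, 1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(InvalidInputError):
            glcm_patch_distribution(np.zeros((32, 32)), GlcmConfig())


class TestLbp:
    def test_constant_image_all_zero_pattern(self):
        h = lbp_histogram(np.full((10, 10), 5.0))
        assert h[0] == 1.0  # the all-zeros uniform pattern is bin 0
        assert h.sum() == pytest.approx(1.0)

    def test_matches_pixelwise_oracle(self, rng):
        for _ in range(100):
            h, w = rng.integers(3, 17, 2)
            img = rng.integers(0, 9, (h, w)).astype(float)
            np.testing.assert_allclose(lbp_histogram(img), oracles.lbp_histogram(img),
                                       atol=1e-12)

    def test_histogram_has_59_bins(self, rng):
        assert len(lbp_histogram(rng.random((16, 16)))) == 59


class TestLpq:
    def test_histogram_normalized_256_bins(self, rng):
        h = lpq_histogram(rng.random((32, 32)))
        assert len(h) == 256
        assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_image_single_code(self):
        h = lpq_histogram(np.full((16, 16), 3.0))
        assert h.max() == 1.0

    def test_near_shift_invariance(self, rng):
        big = np.cumsum(rng.standard_normal((140, 140)), axis=0)  # smooth texture
        a = lpq_histogram(big[3:131, 3:131])
        b = lpq_histogram(big[6:134, 6:134])
        assert np.abs(a - b).sum() < 0.05


class TestGabor:
    def test_constant_image_zero_response(self):
        v = gabor_features(np.full((32, 32), 50.0))
        assert np.abs(v).max() < 1e-9

    def test_grating_dominant_filter(self):
        y = np.arange(64)[:, None] * np.ones((1, 64))
        grating = 50 + 30 * np.sin(2 * np.pi * y / 8)  # horizontal stripes
        means = gabor_features(grating).reshape(4, 3, 2)[:, :, 0]
        assert np.unravel_index(np.argmax(means), means.shape) == (2, 1)  # 90 deg, wl 8

    def test_rotated_grating_swaps_orientation(self):
        x = np.arange(64)[None, :] * np.ones((64, 1))
        grating = 50 + 30 * np.sin(2 * np.pi * x / 8)  # vertical stripes
        means = gabor_features(grating).reshape(4, 3, 2)[:, :, 0]
        assert np.unravel_index(np.argmax(means), means.shape) == (0, 1)  # 0 deg, wl 8


class TestFullVector:
    def test_default_length_and_layout_partition(self, default_scene):
        from woundkit.detect import crop_wound

        img, gt = default_scene
        fv = extract_feature_vector(crop_wound(img, gt.wound_box, 0.1))
        assert len(fv) == 441
        spans = sorted(fv.layout.values())
        assert spans[0][0] == 0 and spans[-1][1] == 441
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c  # contiguous, disjoint

    def test_deterministic(self, default_scene):
        from woundkit.detect import crop_wound

        img, gt = default_scene
        crop = crop_wound(img, gt.wound_box, 0.1)
        a = extract_feature_vector(crop)
        b = extract_feature_vector(crop)
        assert np.array_equal(a.values, b.values)
        assert a.config_hash == b.config_hash

    def test_small_patch_resized_up(self, rng):
        fv = extract_feature_vector(rng.integers(0, 255, (20, 20, 3)))
        assert len(fv) == 441

    def test_csv_round_trip(self, tmp_path, rng):
        fvs = [extract_feature_vector(rng.integers(0, 255, (64, 64, 3))) for _ in range(2)]
        path = tmp_path / "f.csv"
        write_features_csv(path, fvs)
        frame, config_hash = read_features_csv(path)
        assert config_hash == fvs[0].config_hash
        np.testing.assert_allclose(frame.to_numpy()[0], fvs[0].values)


class TestQuantize:
    def test_range_and_constant(self, rng):
        g = rng.random((8, 8))
        q = quantize_gray(g, 16)
        assert q.min() == 0 and q.max() == 15
        assert quantize_gray(np.full((4, 4), 2.0), 8).max() == 0
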