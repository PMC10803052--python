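"""Synthetic lesion generator: determinism, mask statistics, dataset IO,
and image/mask-synchronized augmentation."""

import numpy as np
import pytest
from PIL import Image

from cgmunet import (AugmentConfig, ConfigError, SyntheticConfig,
                     ValidationError, augment, generate_dataset,
                     generate_sample, read_dataset, write_dataset)
from cgmunet.synthetic import rotate_sample


BASE = SyntheticConfig(n_images=4, image_size=(64, 64), seed=3)


class TestDeterminism:
    def test_same_seed_index_bit_identical(self):
        a = generate_sample(BASE, 1)
        b = generate_sample(BASE, 1)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
        assert a.id == b.id

    def test_different_seeds_differ(self):
        other = SyntheticConfig(n_images=4, image_size=(64, 64), seed=4)
        a, b = generate_sample(BASE, 0), generate_sample(other, 0)
        assert not np.array_equal(a.image, b.image)

    def test_different_indices_differ(self):
        a, b = generate_sample(BASE, 0), generate_sample(BASE, 1)
        assert not np.array_equal(a.mask, b.mask) \
            or not np.array_equal(a.image, b.image)


class TestMaskStatistics:
    def test_mask_nonempty_when_lesions_requested(self):
        for i in range(8):
            assert generate_sample(BASE, i).mask.any()

    def test_full_frame_radius_gives_all_ones(self):
        cfg = SyntheticConfig(n_images=1, image_size=(32, 32), seed=0,
                              lesions_per_image=(1, 1),
                              radius_range=(4.0, 4.0))
        assert generate_sample(cfg, 0).mask.all()

    def test_zero_contrast_hides_the_lesion(self):
        """With contrast 0 the foreground has no intensity signature: the
        foreground/background gap collapses compared to a contrasted run."""
        def mean_gap(contrast, n=30):
            cfg = SyntheticConfig(n_images=n, image_size=(128, 128), seed=5,
                                  contrast=contrast, blur_sigma=0.0)
            gaps = []
            for i in range(n):
                s = generate_sample(cfg, i)
                img = s.image[..., 0].astype(float) / 255.0
                gaps.append(img[s.mask == 1].mean() - img[s.mask == 0].mean())
            return float(np.mean(gaps))

        assert abs(mean_gap(0.0)) < 0.1 * mean_gap(0.35)

    def test_foreground_fraction_tracks_analytic_expectation(self):
        """Mean foreground fraction over 200 one-lesion samples stays within
        20% of the expected ellipse area."""
        cfg = SyntheticConfig(n_images=200, image_size=(64, 64), seed=11,
                              lesions_per_image=(1, 1),
                              radius_range=(0.10, 0.25))
        fracs = [generate_sample(cfg, i).mask.mean() for i in range(200)]
        lo, hi = cfg.radius_range
        e_r2 = (lo * lo + lo * hi + hi * hi) / 3.0   # E[r^2], r ~ U(lo, hi)
        e_ecc = 0.8                                   # eccentricity ~ U(0.6, 1)
        expected = np.pi * e_r2 * e_ecc               # area frac of min-dim^2
        assert np.mean(fracs) == pytest.approx(expected, rel=0.20)

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(radius_range=(0.2, 0.1))
        with pytest.raises(ConfigError):
            SyntheticConfig(contrast=1.5)
        with pytest.raises(ConfigError):
            SyntheticConfig(channels=2)


class TestDatasetIO:
    def test_write_read_round_trip(self, tmp_path):
        written = write_dataset(BASE, tmp_path)
        back = read_dataset(tmp_path)
        assert len(back) == len(written) == BASE.n_images
        for a, b in zip(written, back):
            assert a.id == b.id
            assert np.array_equal(a.image, b.image)
            assert np.array_equal(a.mask, b.mask)

    def test_empty_dataset(self, tmp_path):
        cfg = SyntheticConfig(n_images=0, image_size=(32, 32), seed=0)
        write_dataset(cfg, tmp_path)
        assert read_dataset(tmp_path) == []

    def test_missing_mask_warns_and_skips(self, tmp_path):
        write_dataset(BASE, tmp_path)
        victims = sorted((tmp_path / "masks").glob("*.png"))
        victims[0].unlink()
        with pytest.warns(UserWarning, match="without masks"):
            back = read_dataset(tmp_path)
        assert len(back) == BASE.n_images - 1

    def test_non_bilevel_mask_rejected_by_name(self, tmp_path):
        write_dataset(BASE, tmp_path)
        bad = sorted((tmp_path / "masks").glob("*.png"))[0]
        arr = np.asarray(Image.open(bad)).copy()
        arr[0, 0] = 128
        Image.fromarray(arr).save(bad)
        with pytest.raises(ValidationError, match=bad.name):
            read_dataset(tmp_path)


class TestAugmentation:
    def test_identity_config_returns_sample_unchanged(self):
        s = generate_sample(BASE, 0)
        out = augment(s, AugmentConfig(), np.random.default_rng(0))
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.mask, s.mask)

    def test_two_quarter_turns_equal_a_half_turn(self):
        s = generate_sample(BASE, 1)
        twice = rotate_sample(rotate_sample(s, 90), 90)
        once = rotate_sample(s, 180)
        assert np.array_equal(twice.image, once.image)
        assert np.array_equal(twice.mask, once.mask)

    def test_mask_stays_binary_under_any_augmentation(self):
        s = generate_sample(BASE, 2)
        cfg = AugmentConfig(rotate_deg=37.0, brightness=0.3, hue=0.1,
                            crop_scale=0.6)
        rng = np.random.default_rng(5)
        for _ in range(5):
            out = augment(s, cfg, rng)
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.image.dtype == np.uint8
            assert out.image.shape == s.image.shape

    def test_rotation_keeps_image_and_mask_synchronized(self):
        """Lesion centroids measured in the mask and in the image intensity
        move together under rotation (within 1 px)."""
        cfg = SyntheticConfig(n_images=1, image_size=(96, 96), seed=9,
                              lesions_per_image=(1, 1), contrast=0.6,
                              noise_sigma=0.0, blur_sigma=1.0)
        s = generate_sample(cfg, 0)
        rot = rotate_sample(s, 33.0)

        def centroids(sample):
            # background tops out at 0.55, foreground sits near 0.85+
            bright = sample.image[..., 0].astype(float) / 255.0 > 0.7
            yy, xx = np.mgrid[0:bright.shape[0], 0:bright.shape[1]]
            ci = np.array([(yy * bright).sum(), (xx * bright).sum()]) \
                / bright.sum()
            cm = np.array([(yy * sample.mask).sum(),
                           (xx * sample.mask).sum()]) / sample.mask.sum()
            return ci, cm

        ci, cm = centroids(rot)
        assert np.abs(ci - cm).max() < 1.0

    def test_oversized_crop_rejected(self):
        with pytest.raises(ConfigError):
            AugmentConfig(crop_scale=1.5)


def test_generate_dataset_length_and_ids_unique():
    samples = generate_dataset(BASE)
    assert len(samples) == BASE.n_images
    assert len({s.id for s in samples}) == BASE.n_images
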