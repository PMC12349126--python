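"""Synthetic generator determinism/statistics and dataset I/O."""

import warnings

import numpy as np
import pytest
from PIL import Image

from sgnet.data import (SegSample, SynthConfig, augment, generate_dataset,
                        generate_sample, read_isic_folder, to_batch,
                        write_sample, write_synthetic_dataset)


class TestGenerator:
    def test_same_seed_index_is_bitwise_identical(self):
        cfg = SynthConfig(image_size=64, seed=11)
        a = generate_sample(cfg, 3)
        b = generate_sample(cfg, 3)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_different_indices_differ(self):
        cfg = SynthConfig(image_size=64, seed=11)
        a = generate_sample(cfg, 0)
        b = generate_sample(cfg, 1)
        assert not np.array_equal(a.mask, b.mask)

    def test_mask_binary_and_image_in_unit_range(self):
        cfg = SynthConfig(image_size=64, seed=2)
        s = generate_sample(cfg, 0)
        assert set(np.unique(s.mask)) <= {0, 1}
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0
        assert s.image.dtype == np.float32

    def test_zero_hair_range_draws_no_hair(self):
        """With hair_count_range=(0,0) the hair stage is inert: thickness
        settings cannot influence the image."""
        a = generate_sample(SynthConfig(image_size=64, seed=3,
                                        hair_count_range=(0, 0),
                                        hair_thickness_range=(1, 1)), 1)
        b = generate_sample(SynthConfig(image_size=64, seed=3,
                                        hair_count_range=(0, 0),
                                        hair_thickness_range=(3, 3)), 1)
        assert np.array_equal(a.image, b.image)
        c = generate_sample(SynthConfig(image_size=64, seed=3,
                                        hair_count_range=(6, 6)), 1)
        assert not np.array_equal(a.image, c.image)

    def test_mean_foreground_fraction_within_configured_bounds(self):
        """Monte-Carlo check that lesion area matches the axis-range implied
        ellipse-area bounds (pi*lo^2 .. pi*hi^2 as a fraction of the image)."""
        cfg = SynthConfig(image_size=96, seed=4, n_samples=300)
        fracs = [generate_sample(cfg, i).mask.mean() for i in range(300)]
        lo, hi = cfg.lesion_axis_range
        assert np.pi * lo ** 2 * 0.5 < np.mean(fracs) < np.pi * hi ** 2 * 1.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(lesion_axis_range=(0.5, 0.6))
        with pytest.raises(ValueError):
            SynthConfig(contrast_delta=0.0)
        with pytest.raises(ValueError):
            SynthConfig(hair_count_range=(5, 2))


class TestAugmentation:
    def test_identity_draw_leaves_sample_unchanged(self):
        cfg = SynthConfig(image_size=64, seed=5)
        s = generate_sample(cfg, 0)

        class FakeRng:
            def random(self):
                return 0.9          # > 0.5: no flip
            def integers(self, lo, hi):
                return 0            # no rotation
        out = augment(s, rng=FakeRng())
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.mask, s.mask)

    def test_double_horizontal_flip_is_involution(self):
        cfg = SynthConfig(image_size=64, seed=6)
        s = generate_sample(cfg, 0)
        flipped = SegSample(np.ascontiguousarray(np.flip(s.image, 2)),
                            np.ascontiguousarray(np.flip(s.mask, 2)))
        back = SegSample(np.ascontiguousarray(np.flip(flipped.image, 2)),
                         np.ascontiguousarray(np.flip(flipped.mask, 2)))
        assert np.array_equal(back.image, s.image)

    @pytest.mark.parametrize("seed", range(4))
    def test_foreground_count_invariant_under_augmentation(self, seed):
        cfg = SynthConfig(image_size=64, seed=7)
        s = generate_sample(cfg, seed)
        out = augment(s, rng=np.random.default_rng(seed))
        assert out.mask.sum() == s.mask.sum()
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_augmentation_is_seed_deterministic(self):
        cfg = SynthConfig(image_size=64, seed=8)
        s = generate_sample(cfg, 0)
        a = augment(s, rng=np.random.default_rng(42))
        b = augment(s, rng=np.random.default_rng(42))
        assert np.array_equal(a.image, b.image)


class TestIO:
    def test_png_roundtrip_recovers_mask_bit_exactly(self, tmp_path):
        cfg = SynthConfig(image_size=64, seed=9)
        s = generate_sample(cfg, 0)
        write_sample(s, tmp_path / "img.png", tmp_path / "msk.png")
        from sgnet.data import read_pair
        back = read_pair(tmp_path / "img.png", tmp_path / "msk.png", size=64)
        assert np.array_equal(back.mask, s.mask)
        assert np.abs(back.image - s.image).max() <= 1 / 255 + 1e-6

    def test_isic_folder_reading_and_pairing(self, tmp_path):
        root = tmp_path / "data"
        cfg = SynthConfig(image_size=64, seed=10)
        (root / "train" / "images").mkdir(parents=True)
        (root / "train" / "masks").mkdir(parents=True)
        for i in range(4):
            s = generate_sample(cfg, i)
            write_sample(s, root / "train" / "images" / f"im{i}.png",
                         root / "train" / "masks" / f"im{i}_segmentation.png")
        # one unpaired image must be skipped with a warning
        s = generate_sample(cfg, 99)
        Image.fromarray((s.image.transpose(1, 2, 0) * 255).astype(np.uint8)) \
            .save(root / "train" / "images" / "orphan.png")
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            samples = read_isic_folder(root, "train", size=64)
        assert len(samples) == 4
        assert any("orphan" in str(w.message) for w in rec)

    def test_masks_binarized_at_midpoint(self, tmp_path):
        arr = np.zeros((32, 32), dtype=np.uint8)
        arr[:16] = 255
        arr[16:20] = 100          # below 127 -> background
        root = tmp_path / "d"
        (root / "test" / "images").mkdir(parents=True)
        (root / "test" / "masks").mkdir(parents=True)
        Image.fromarray(np.zeros((32, 32, 3), dtype=np.uint8)) \
            .save(root / "test" / "images" / "a.png")
        Image.fromarray(arr).save(root / "test" / "masks" / "a.png")
        sample = read_isic_folder(root, "test", size=32)[0]
        assert sample.mask[0, :16].all() and not sample.mask[0, 16:].any()

    def test_empty_split_raises(self, tmp_path):
        (tmp_path / "val" / "images").mkdir(parents=True)
        (tmp_path / "val" / "masks").mkdir(parents=True)
        with pytest.raises(ValueError, match="no paired"):
            read_isic_folder(tmp_path, "val")
        with pytest.raises(FileNotFoundError):
            read_isic_folder(tmp_path, "missing")

    def test_write_synthetic_dataset_manifest(self, tmp_path):
        cfg = SynthConfig(n_samples=3, image_size=64, seed=12)
        manifest = write_synthetic_dataset(cfg, tmp_path / "synth")
        lines = manifest.read_text().strip().splitlines()
        assert len(lines) == 4          # header + 3 rows
        imgs = list((tmp_path / "synth" / "images").iterdir())
        masks = list((tmp_path / "synth" / "masks").iterdir())
        assert len(imgs) == 3 and len(masks) == 3

    def test_to_batch_shapes(self):
        cfg = SynthConfig(image_size=64, seed=13)
        images, masks = to_batch([generate_sample(cfg, i) for i in range(2)])
        assert images.shape == (2, 3, 64, 64)
        assert masks.shape == (2, 1, 64, 64)
        assert images.dtype == np.float32
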