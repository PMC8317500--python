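"""Synthetic scenes, augmentation, I/O and splitting."""

import numpy as np
import pytest

import mbffnet as mb
from mbffnet.data import (
    AugmentationConfig,
    SegmentationSample,
    SyntheticSceneSpec,
    augment,
    generate_dataset,
    generate_scene,
    load_dataset,
    load_sample,
    save_sample,
    split,
    write_dataset,
)


class TestSyntheticScenes:
    def test_seed_determinism(self):
        spec = SyntheticSceneSpec(side=64, seed=11)
        a, b = generate_scene(spec), generate_scene(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_single_blob_area_matches_ellipse(self):
        """One blob of radius fraction 0.2 covers ~pi*0.2^2 of the frame
        (the semi-axes are r*sqrt(e), r/sqrt(e), so area is exactly
        pi*r^2 up to pixelation)."""
        fracs = []
        for seed in range(10):
            spec = SyntheticSceneSpec(
                side=64, blob_count=(1, 1), blob_radius=(0.2, 0.2), seed=seed
            )
            fracs.append(generate_scene(spec).mask.mean())
        assert all(0.08 <= f <= 0.17 for f in fracs)
        assert np.mean(fracs) == pytest.approx(np.pi * 0.04, rel=0.08)

    def test_noiseless_limit_thresholds_to_mask(self):
        spec = SyntheticSceneSpec(
            side=64,
            blob_count=(1, 1),
            background_intensity=0.0,
            foreground_intensity=1.0,
            texture_noise_sd=0.0,
            edge_softness=0.0,
            seed=4,
        )
        s = generate_scene(spec)
        thresholded = (s.image.mean(axis=-1) > 0.5).astype(np.uint8)
        # channel tints keep the interior above 0.5 and background at ~0
        assert (thresholded == s.mask).mean() > 0.995

    def test_foreground_fraction_statistics(self):
        """Mean foreground fraction over many seeds matches the analytic
        expectation E[pi r^2] for one blob within 3 standard errors."""
        r0, r1 = 0.10, 0.25
        spec = SyntheticSceneSpec(side=64, blob_count=(1, 1), blob_radius=(r0, r1))
        fracs = np.array(
            [generate_scene(SyntheticSceneSpec(side=64, blob_count=(1, 1),
                                               blob_radius=(r0, r1), seed=s)).mask.mean()
             for s in range(500)]
        )
        expect = np.pi * (r0**2 + r0 * r1 + r1**2) / 3
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expect) < 3 * se + 0.005  # + pixelation bias

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSceneSpec(side=16)
        with pytest.raises(ValueError):
            SyntheticSceneSpec(blob_radius=(0.0, 0.3))

    def test_dataset_seeds_differ(self):
        samples = generate_dataset(SyntheticSceneSpec(side=64), 4, seed=5)
        assert len({s.image.tobytes() for s in samples}) == 4

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = SyntheticSceneSpec(side=96, seed=7)
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        assert SyntheticSceneSpec.from_yaml(p) == spec


class TestAugmentation:
    def test_identity_configuration(self, scene64):
        out = augment(scene64, AugmentationConfig.identity(), seed=0)
        assert np.array_equal(out.image, scene64.image)
        assert np.array_equal(out.mask, scene64.mask)

    def test_horizontal_flip_mirrors_centroid(self, scene64):
        cfg = AugmentationConfig(
            brightness_range=(0, 0), zoom_range=(1, 1), hflip_prob=1.0,
            shift_frac=0.0, rotation_range=(0, 0), channel_shift=0.0,
        )
        out = augment(scene64, cfg, seed=0)
        w = scene64.mask.shape[1]
        cx = np.nonzero(scene64.mask)[1].mean()
        cx_f = np.nonzero(out.mask)[1].mean()
        assert cx_f == pytest.approx(w - 1 - cx, abs=0.51)

    def test_seeded_determinism(self, scene64):
        a = augment(scene64, seed=42)
        b = augment(scene64, seed=42)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_output_contracts(self, scene64):
        """Any draw keeps the size, mask binarity and image range."""
        for seed in range(8):
            out = augment(scene64, seed=seed)
            assert out.image.shape == scene64.image.shape
            assert out.mask.shape == scene64.mask.shape
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_geometric_consistency(self, scene64):
        """Image and mask share one transform: a blob centred in the
        image stays under the mask after any geometric draw."""
        for seed in range(5):
            out = augment(scene64, seed=seed)
            if out.mask.sum() == 0:
                continue
            inside = out.image.mean(axis=-1)[out.mask == 1].mean()
            outside = out.image.mean(axis=-1)[out.mask == 0].mean()
            assert inside > outside  # polyps stay brighter than background


class TestSplitAndIO:
    def test_published_split_arithmetic(self):
        train, test = split(list(range(1450)), 0.8, seed=0)
        assert (len(train), len(test)) == (1160, 290)

    def test_split_disjoint_exhaustive(self):
        train, test = split(list(range(10)), 0.8, seed=3)
        assert len(train) == 8 and len(test) == 2
        assert sorted(train + test) == list(range(10))

    def test_split_seeded(self):
        a = split(list(range(20)), seed=9)
        b = split(list(range(20)), seed=9)
        assert a == b

    def test_split_too_small(self):
        with pytest.raises(ValueError):
            split([1], 0.8, seed=0)

    def test_sample_round_trip(self, tmp_path, scene64):
        ip, mp = tmp_path / "img.png", tmp_path / "msk.png"
        save_sample(scene64, ip, mp)
        back = load_sample(ip, mp)
        assert np.array_equal(back.mask, scene64.mask)
        assert np.allclose(back.image, scene64.image, atol=1 / 255)

    def test_load_resamples_to_target(self, tmp_path, scene64):
        ip, mp = tmp_path / "img.png", tmp_path / "msk.png"
        save_sample(scene64, ip, mp)
        back = load_sample(ip, mp, target_size=32)
        assert back.image.shape == (32, 32, 3)
        assert back.mask.shape == (32, 32)

    def test_size_mismatch_rejected(self, tmp_path, scene64):
        from PIL import Image

        ip, mp = tmp_path / "img.png", tmp_path / "msk.png"
        save_sample(scene64, ip, mp)
        Image.new("L", (32, 32)).save(mp)
        with pytest.raises(ValueError):
            load_sample(ip, mp)

    def test_dataset_directory_round_trip(self, tmp_path):
        samples = generate_dataset(SyntheticSceneSpec(side=64), 3, seed=2)
        write_dataset(samples, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert len(back) == 3
        assert np.array_equal(back[0].mask, samples[0].mask)

    def test_mismatched_mask_values_rejected(self):
        with pytest.raises(ValueError):
            SegmentationSample(np.zeros((4, 4, 3)), np.full((4, 4), 2))
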