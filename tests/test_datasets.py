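"""Binning, stratified splitting and label-preserving augmentation."""

import numpy as np
import pytest

import countreg as cr
from countreg.data import squeeze_resize

from conftest import component_count, dummy_dataset


class TestAssignBins:
    def test_equal_width_over_hundred_labels(self):
        ds = dummy_dataset(range(100))
        binned = cr.assign_bins(ds, 20)
        # width (99 - 0 + 1)/20 = 5
        assert binned.label_bins[0] == 0
        assert binned.label_bins[4] == 0
        assert binned.label_bins[5] == 1
        assert binned.label_bins[99] == 19

    def test_single_bin(self):
        binned = cr.assign_bins(dummy_dataset([1, 5, 9]), 1)
        assert (binned.label_bins == 0).all()

    def test_ring_range_fills_eight_contiguous_bins(self):
        ds = dummy_dataset(list(range(1, 64)) * 3)
        binned = cr.assign_bins(ds, 8)
        present = np.unique(binned.label_bins)
        assert np.array_equal(present, np.arange(8))
        # monotone in the label
        order = np.argsort(binned.labels)
        assert (np.diff(binned.label_bins[order]) >= 0).all()

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cr.assign_bins(dummy_dataset([4, 4, 4]), 2)


class TestStratifiedSplit:
    def test_otolith_style_sizes(self):
        ds = dummy_dataset([(i % 63) + 1 for i in range(3585)])
        test, rem = cr.stratified_test_split(ds, cr.SplitSpec(n_bins=8, per_bin=15, seed=0))
        assert len(test) == 120
        assert len(rem) == 3465

    def test_seal_style_sizes(self):
        ds = dummy_dataset([i % 100 for i in range(11_087)])
        test, rem = cr.stratified_test_split(ds, cr.SplitSpec(n_bins=20, per_bin=5, seed=0))
        assert len(test) == 100
        assert len(rem) == 10_987

    def test_zero_per_bin(self):
        ds = dummy_dataset(range(40))
        test, rem = cr.stratified_test_split(ds, cr.SplitSpec(n_bins=4, per_bin=0, seed=0))
        assert len(test) == 0
        assert rem.ids == ds.ids

    def test_underpopulated_bin_names_the_bin(self):
        ds = dummy_dataset([0] * 30 + [9])
        with pytest.raises(ValueError, match="bin 1"):
            cr.stratified_test_split(ds, cr.SplitSpec(n_bins=4, per_bin=2, seed=0))

    @pytest.mark.parametrize("trial", range(20))
    def test_partition_and_exact_stratification(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(60, 200))
        ds = dummy_dataset(rng.integers(0, 30, size=n), prefix=f"t{trial}")
        n_bins, per_bin = int(rng.integers(1, 5)), int(rng.integers(0, 4))
        binned = cr.assign_bins(ds, n_bins)
        counts = np.bincount(binned.label_bins, minlength=n_bins)
        if counts.min() < per_bin:
            return
        test, rem = cr.stratified_test_split(
            binned, cr.SplitSpec(n_bins=n_bins, per_bin=per_bin, seed=trial)
        )
        assert sorted(test.ids + rem.ids) == sorted(ds.ids)
        assert not set(test.ids) & set(rem.ids)
        assert np.array_equal(
            np.bincount(test.label_bins, minlength=n_bins),
            np.full(n_bins, per_bin),
        )

    def test_seeded_determinism(self):
        ds = dummy_dataset([i % 10 for i in range(200)])
        spec = cr.SplitSpec(n_bins=5, per_bin=3, seed=11)
        t1, _ = cr.stratified_test_split(ds, spec)
        t2, _ = cr.stratified_test_split(ds, spec)
        assert t1.ids == t2.ids


class TestTrainValSplit:
    @pytest.mark.parametrize(
        "n,frac,n_train", [(3465, 0.8, 2772), (10, 0.8, 8), (887, 0.8, 709)]
    )
    def test_floor_rule_sizes(self, n, frac, n_train):
        train, val = cr.train_val_split(dummy_dataset(range(n)), frac, seed=0)
        assert len(train) == n_train
        assert len(val) == n - n_train

    def test_partition_and_determinism(self):
        ds = dummy_dataset(range(57))
        t1, v1 = cr.train_val_split(ds, 0.8, seed=5)
        t2, v2 = cr.train_val_split(ds, 0.8, seed=5)
        assert t1.ids == t2.ids and v1.ids == v2.ids
        assert sorted(t1.ids + v1.ids) == sorted(ds.ids)
        t3, _ = cr.train_val_split(ds, 0.8, seed=6)
        assert t3.ids != t1.ids


class TestAugment:
    def test_identity_policy_is_squeeze_resize_only(self, noiseless_dot_spec):
        im = cr.generate_dot_scene(noiseless_dot_spec, 6, seed=1)
        policy = cr.AugmentationPolicy(
            horizontal_flip_probability=0.0,
            lighting_jitter_range=(1.0, 1.0),
            warp_magnitude=0.0,
            max_zoom_fraction=0.0,
        )
        out = cr.augment(im, policy, np.random.default_rng(0))
        assert np.array_equal(out.pixels, im.pixels)
        assert out.label == im.label

    def test_flip_mirrors_pixels_and_keeps_label(self, noiseless_dot_spec):
        im = cr.generate_dot_scene(noiseless_dot_spec, 6, seed=2)
        policy = cr.AugmentationPolicy(
            horizontal_flip_probability=1.0,
            lighting_jitter_range=(1.0, 1.0),
            max_zoom_fraction=0.0,
        )
        out = cr.augment(im, policy, np.random.default_rng(0))
        assert np.array_equal(out.pixels, im.pixels[:, ::-1])
        assert out.label == im.label

    def test_output_always_at_target_size(self):
        im = cr.LabelledImage(
            pixels=np.random.default_rng(0).random((96, 80)).astype(np.float32),
            label=0, id="odd",
        )
        policy = cr.AugmentationPolicy(target_height=64, target_width=64, warp_magnitude=0.02)
        out = cr.augment(im, policy, np.random.default_rng(1))
        assert out.pixels.shape == (64, 64)

    def test_component_oracle_survives_augmentation(self, noiseless_dot_spec):
        """1000 augmented noiseless scenes: the count never changes."""
        policy = cr.AugmentationPolicy(
            horizontal_flip_probability=0.5,
            lighting_jitter_range=(0.85, 1.15),
            warp_magnitude=0.02,
            max_zoom_fraction=0.1,
        )
        rng = np.random.default_rng(123)
        failures = 0
        for scene_idx in range(250):
            count = (scene_idx * 3) % 31
            im = cr.generate_dot_scene(noiseless_dot_spec, count, seed=scene_idx)
            for _ in range(4):
                out = cr.augment(im, policy, rng)
                if component_count(out.pixels) != count:
                    failures += 1
        assert failures == 0

    def test_empty_image_rejected(self):
        im = cr.LabelledImage(pixels=np.zeros((0, 0)), label=0, id="e")
        with pytest.raises(ValueError, match="empty"):
            cr.augment(im, cr.AugmentationPolicy(), np.random.default_rng(0))


def test_squeeze_resize_never_crops():
    px = np.zeros((40, 80), dtype=np.float32)
    px[0, 0] = px[-1, -1] = 1.0  # corner content survives a squeeze
    out = squeeze_resize(px, 20, 20)
    assert out.shape == (20, 20)
    assert out[0, 0] > 0 and out[-1, -1] > 0


def test_dataset_rejects_duplicate_ids():
    im = cr.LabelledImage(pixels=np.zeros((1, 1)), label=0, id="same")
    with pytest.raises(ValueError, match="duplicate"):
        cr.CountDataset([im, im])
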