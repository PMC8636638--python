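"""Generators: seeded determinism, exact count fidelity, noise and oracle."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates
from scipy.stats import chisquare

import countreg as cr
from countreg.synthetic import UNIDENTIFIABLE, sample_counts

from conftest import component_count, dummy_dataset


class TestDotScenes:
    def test_empty_scene_has_no_foreground(self, noiseless_dot_spec):
        im = cr.generate_dot_scene(noiseless_dot_spec, 0, seed=7)
        assert im.label == 0
        assert component_count(im.pixels) == 0
        assert not im.meta["object_mask"].any()

    def test_seeded_determinism(self):
        spec = cr.DotSceneSpec()
        a = cr.generate_dot_scene(spec, 25, seed=1)
        b = cr.generate_dot_scene(spec, 25, seed=1)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.label == b.label == 25
        c = cr.generate_dot_scene(spec, 25, seed=2)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_count_out_of_range_rejected(self, noiseless_dot_spec):
        with pytest.raises(ValueError, match="count_range"):
            cr.generate_dot_scene(noiseless_dot_spec, 31, seed=0)

    @pytest.mark.parametrize("seed", range(40))
    def test_component_count_equals_label(self, noiseless_dot_spec, seed):
        count = (seed * 7) % 31
        im = cr.generate_dot_scene(noiseless_dot_spec, count, seed=seed)
        assert component_count(im.pixels) == count == im.label

    def test_distractors_do_not_enter_the_count(self):
        spec = cr.DotSceneSpec(
            background_texture_amplitude=0.0,
            lighting_jitter=(1.0, 1.0),
            distractor_count_range=(2, 2),
        )
        im = cr.generate_dot_scene(spec, 5, seed=11)
        assert im.label == 5
        assert im.meta["distractor_mask"].any()


class TestRingImages:
    def _radial_peaks(self, image):
        """Independent oracle: local maxima of the radial profile."""
        h, w = image.pixels.shape
        cy, cx = (h - 1) / 2, (w - 1) / 2
        radii = np.arange(0.0, min(h, w) / 2 - 1, 0.25)
        # average over several directions to suppress sampling jitter
        profs = []
        for ang in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            ys, xs = cy + radii * np.sin(ang), cx + radii * np.cos(ang)
            profs.append(map_coordinates(image.pixels, [ys, xs], order=1))
        prof = np.mean(profs, axis=0)
        agc = image.meta["agc_radius"]
        peaks = [
            i
            for i in range(1, len(prof) - 1)
            if prof[i] > prof[i - 1] and prof[i] > prof[i + 1] and radii[i] > agc
        ]
        return len(peaks)

    def test_minimal_ring_outside_agc(self):
        spec = cr.RingImageSpec(
            image_height=160, image_width=160, ring_spacing=5.0,
            ring_count_range=(1, 12), agc_radius=12.0,
        )
        im = cr.generate_ring_image(spec, 1, seed=3)
        assert im.label == 1
        assert self._radial_peaks(im) == 1
        assert (im.meta["ring_radii"] > im.meta["agc_radius"]).all()

    def test_radial_profile_counts_twenty_rings(self):
        spec = cr.RingImageSpec(
            image_height=160, image_width=160, ring_spacing=3.0,
            ring_count_range=(1, 22), agc_radius=10.0,
        )
        im = cr.generate_ring_image(spec, 20, seed=5)
        assert self._radial_peaks(im) == 20

    def test_seeded_determinism(self):
        spec = cr.RingImageSpec()
        a = cr.generate_ring_image(spec, 40, seed=9)
        b = cr.generate_ring_image(spec, 40, seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_overflowing_pattern_rejected(self):
        with pytest.raises(ValueError, match="half-width"):
            cr.RingImageSpec(image_height=64, image_width=64)  # 63 rings cannot fit
        spec = cr.RingImageSpec(
            image_height=64, image_width=64, ring_count_range=(1, 10), ring_spacing=2.0,
            agc_radius=8.0,
        )
        im = cr.generate_ring_image(spec, 10, seed=0)
        assert im.label == 10


class TestMakeDataset:
    def test_degenerate_distribution(self):
        spec = cr.DotSceneSpec(image_height=24, image_width=24, count_range=(0, 6))
        ds = cr.make_dataset(spec, 30, {5: 1.0}, seed=0)
        assert (ds.labels == 5).all()

    def test_label_sequence_matches_sampler_and_is_deterministic(self):
        spec = cr.DotSceneSpec(image_height=24, image_width=24, count_range=(0, 6))
        w = cr.geometric_weights(0, 6)
        ds1 = cr.make_dataset(spec, 40, w, seed=3)
        ds2 = cr.make_dataset(spec, 40, w, seed=3)
        assert np.array_equal(ds1.labels, ds2.labels)
        assert np.array_equal(ds1.labels, sample_counts(w, 40, 3))
        assert np.array_equal(ds1.items[0].pixels, ds2.items[0].pixels)

    def test_monte_carlo_mean_of_sampled_labels(self):
        w = cr.geometric_weights(0, 99, decay=0.9)
        counts = np.array(sorted(w))
        p = np.array([w[c] for c in counts], dtype=float)
        p /= p.sum()
        mu = float((counts * p).sum())
        sd = float(np.sqrt(((counts - mu) ** 2 * p).sum()))
        draws = sample_counts(w, 10_000, seed=42)
        assert abs(draws.mean() - mu) < 3 * sd / np.sqrt(10_000)

    def test_chi_square_goodness_of_fit(self):
        w = {c: float(v) for c, v in zip(range(10), [5, 4, 3, 3, 2, 2, 1, 1, 0.5, 0.5])}
        draws = sample_counts(w, 10_000, seed=1)
        total = sum(w.values())
        expected = np.array([w[c] / total * 10_000 for c in sorted(w)])
        observed = np.bincount(draws, minlength=10)
        assert chisquare(observed, expected).pvalue > 0.01

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            sample_counts({0: 0.0, 1: 0.0}, 5, 0)
        with pytest.raises(ValueError):
            sample_counts({0: -1.0, 1: 2.0}, 5, 0)


class TestLabelNoise:
    def test_zero_probability_is_identity(self):
        ds = dummy_dataset([3, 7, 12])
        noisy = cr.corrupt_labels(ds, cr.LabelNoiseModel(corruption_probability=0.0), seed=0)
        assert np.array_equal(noisy.labels, ds.labels)
        assert not any(im.noisy for im in noisy)

    def test_forced_half_retention(self):
        ds = dummy_dataset([10])
        noise = cr.LabelNoiseModel(
            corruption_probability=1.0, retained_fraction_range=(0.5, 0.5)
        )
        noisy = cr.corrupt_labels(ds, noise, seed=0)
        assert noisy.labels[0] == 5
        assert noisy.items[0].true_label == 10
        assert noisy.items[0].noisy

    def test_undercount_only_and_preserved_truth(self):
        rng = np.random.default_rng(0)
        ds = dummy_dataset(rng.integers(0, 60, size=500))
        noisy = cr.corrupt_labels(ds, cr.LabelNoiseModel(), seed=1)
        truth = ds.labels
        assert (noisy.labels <= truth).all()
        assert (noisy.labels >= 0).all()
        for im, t in zip(noisy, truth):
            assert im.true_label == t
            if not im.noisy:
                assert im.label == t

    def test_monte_carlo_retained_fraction(self):
        ds = dummy_dataset([1000] * 10_000)
        noise = cr.LabelNoiseModel(
            corruption_probability=1.0, retained_fraction_range=(0.3, 0.9)
        )
        noisy = cr.corrupt_labels(ds, noise, seed=2)
        ratios = noisy.labels / 1000.0
        se = np.sqrt(0.6**2 / 12) / np.sqrt(10_000)  # Uniform(0.3,0.9) std err
        assert abs(ratios.mean() - 0.6) < 3 * se + 1e-3  # +floor-rounding slack


class TestOracle:
    def test_passthrough_and_flag(self):
        visible = dummy_dataset([12])[0]
        assert cr.oracle_relabel(visible) == 12
        flagged = dummy_dataset([12], unidentifiable=True)[0]
        assert cr.oracle_relabel(flagged) is UNIDENTIFIABLE

    def test_thirty_five_flagged_images_yield_thirty_five_signals(self):
        flags = [True] * 35 + [False] * 65
        ds = cr.CountDataset(
            [
                cr.LabelledImage(
                    pixels=np.zeros((1, 1)), label=i % 9, true_label=i % 9,
                    id=f"p-{i}", unidentifiable=f,
                )
                for i, f in enumerate(flags)
            ]
        )
        results = [cr.oracle_relabel(im) for im in ds]
        assert sum(r is UNIDENTIFIABLE for r in results) == 35

    def test_noisy_image_without_truth_fails(self):
        im = cr.LabelledImage(pixels=np.zeros((1, 1)), label=3, id="x", noisy=True)
        with pytest.raises(ValueError, match="true-label"):
            cr.oracle_relabel(im)

    def test_scale_threshold_flags_unidentifiable(self, noiseless_dot_spec):
        im = cr.generate_dot_scene(noiseless_dot_spec, 5, seed=0)
        ds = cr.CountDataset([im])
        noise = cr.LabelNoiseModel(
            corruption_probability=0.0, unidentifiable_scale_threshold=0.99
        )
        assert cr.corrupt_labels(ds, noise, seed=0).items[0].unidentifiable
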