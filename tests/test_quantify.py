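"""Thresholding, segmentation, and particle measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ihcquant import (
    SyntheticConfig,
    auto_threshold,
    detect_particles,
    estimate_tissue_mask,
    generate_sample,
    invert_signal,
    quantify_image,
    quantify_sample,
    segment_positive,
)
from ihcquant.quantify import DegenerateHistogramError, EmptyTissueError, triangle_threshold


def brute_force_otsu(values, n_bins):
    """Independent oracle: exhaustive search over every interior bin edge for
    the one maximizing between-class variance of the histogram, ties low."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    variances = np.full(n_bins - 1, -np.inf)
    for k in range(1, n_bins):
        w0 = counts[:k].sum()
        w1 = counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        variances[k - 1] = w0 * w1 * (mu0 - mu1) ** 2
    vmax = variances.max()
    # mathematical ties (edges across empty bins) go to the lowest edge;
    # tolerance keeps summation-order noise from deciding a tie
    best = int(np.flatnonzero(variances >= vmax - 1e-10 * abs(vmax))[0])
    return edges[best + 1]


class TestInvertSignal:
    def test_constant_image_inverts_to_zero(self):
        assert np.array_equal(invert_signal(np.full((3, 3), 7.0)), np.zeros((3, 3)))

    def test_small_example(self):
        out = invert_signal(np.array([0.0, 1.0, 3.0]))
        assert np.array_equal(out, [3.0, 2.0, 0.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.float64, (4, 5), elements=st.floats(-50, 50)))
    def test_involution_up_to_baseline(self, x):
        """Double inversion reproduces the image up to its baseline:
        invert(invert(x)) == x - min(x), exact when min(x) == 0."""
        twice = invert_signal(invert_signal(x))
        assert twice == pytest.approx(x - x.min(), abs=1e-12)

    def test_exact_involution_for_zero_baseline(self, rng):
        x = rng.uniform(0, 3, (6, 6))
        x.flat[0] = 0.0
        assert invert_signal(invert_signal(x)) == pytest.approx(x, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            invert_signal(np.array([1.0, np.inf]))


class TestAutoThreshold:
    def test_bimodal_split_separates_classes(self):
        values = np.concatenate([np.full(100, 10.0), np.full(100, 200.0)])
        t = auto_threshold(values)
        assert 10.0 < t < 200.0

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            auto_threshold(np.full((8, 8), 3.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        size = rng.integers(4, 65)
        values = rng.normal(0, 1, size) + rng.choice([0, 3], size)
        assert auto_threshold(values, n_bins=16) == brute_force_otsu(values, 16)

    def test_shift_equivariance(self, rng):
        values = rng.uniform(0, 5, 200)
        t = auto_threshold(values, n_bins=32)
        assert auto_threshold(values + 100.0, n_bins=32) == pytest.approx(t + 100.0, abs=1e-9)

    def test_close_to_skimage_otsu(self, rng):
        """Independent oracle: within one bin of scikit-image's Otsu (which
        returns a bin center where this implementation returns an edge)."""
        from skimage.filters import threshold_otsu

        values = np.concatenate([rng.normal(0.1, 0.05, 800), rng.normal(1.0, 0.1, 200)])
        t = auto_threshold(values, n_bins=256)
        ref = threshold_otsu(values, nbins=256)
        bin_width = (values.max() - values.min()) / 256
        assert abs(t - ref) <= bin_width


class TestTriangleThreshold:
    def test_skewed_histogram_threshold_between_peak_and_tail(self, rng):
        values = np.concatenate([rng.normal(0.05, 0.02, 900), rng.uniform(0.5, 1.0, 100)])
        t = triangle_threshold(values)
        assert 0.05 < t < 1.0

    def test_constant_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            triangle_threshold(np.ones(10))


class TestSegmentPositive:
    def test_threshold_above_max_empty(self):
        tissue = np.ones((4, 4), dtype=bool)
        assert not segment_positive(np.ones((4, 4)), tissue, 2.0).any()

    def test_negative_threshold_fills_tissue(self):
        tissue = np.zeros((4, 4), dtype=bool)
        tissue[1:3, 1:3] = True
        mask = segment_positive(np.zeros((4, 4)), tissue, -1.0)
        assert np.array_equal(mask, tissue)

    def test_negative_concentrations_treated_as_zero(self):
        tissue = np.ones((1, 3), dtype=bool)
        mask = segment_positive(np.array([[-5.0, 0.1, 0.5]]), tissue, 0.2)
        assert mask.tolist() == [[False, False, True]]

    def test_empty_tissue_rejected(self):
        with pytest.raises(EmptyTissueError):
            segment_positive(np.ones((2, 2)), np.zeros((2, 2), dtype=bool), 0.5)


class TestDetectParticles:
    def test_empty_mask(self):
        assert detect_particles(np.zeros((5, 5), dtype=bool)) == []

    def test_three_disjoint_squares(self):
        mask = np.zeros((20, 20), dtype=bool)
        for r, c in [(0, 0), (0, 12), (12, 6)]:
            mask[r : r + 5, c : c + 5] = True
        particles = detect_particles(mask, min_particle_size=1)
        assert len(particles) == 3
        assert all(p.pixel_count == 25 for p in particles)
        assert [p.label for p in particles] == [1, 2, 3]

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(detect_particles(mask, connectivity=8, min_particle_size=1)) == 1
        assert len(detect_particles(mask, connectivity=4, min_particle_size=1)) == 2

    def test_min_size_filter_and_relabel(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True  # 1 px, filtered
        mask[4:6, 4:6] = True  # 4 px, kept
        particles = detect_particles(mask, min_particle_size=4)
        assert [p.label for p in particles] == [1]
        assert particles[0].centroid == (4.5, 4.5)

    def test_integrated_od_sums_intensity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        intensity = np.full((4, 4), 0.5)
        (p,) = detect_particles(mask, min_particle_size=1, intensity=intensity)
        assert p.integrated_od == pytest.approx(2.0)


class TestQuantifySample:
    def test_no_particles(self):
        tissue = np.ones((10, 10), dtype=bool)
        m = quantify_sample(np.zeros((10, 10)), tissue, [], threshold=0.3)
        assert (m.particle_count, m.dab_area_fraction, m.mean_dab_od) == (0, 0.0, 0.0)

    def test_single_uniform_particle_arithmetic(self):
        tissue = np.zeros((40, 25), dtype=bool)
        tissue.ravel()[:1000] = True
        dab = np.zeros((40, 25))
        dab[0:5, 0:5] = 0.8
        mask = dab > 0.4
        particles = detect_particles(mask & tissue, min_particle_size=1, intensity=dab)
        m = quantify_sample(dab, tissue, particles, threshold=0.4)
        assert m.dab_area_fraction == pytest.approx(0.025)
        assert m.integrated_dab_od == pytest.approx(20.0)
        assert m.mean_dab_od == pytest.approx(0.8)

    def test_empty_tissue_rejected(self):
        with pytest.raises(EmptyTissueError):
            quantify_sample(np.zeros((2, 2)), np.zeros((2, 2), dtype=bool), [], 0.1)


def small(**kw):
    base = dict(image_height=160, image_width=160, nucleus_count=30, noise_sd=0.0)
    base.update(kw)
    return SyntheticConfig(**base)


class TestTissueMask:
    def test_all_white_image_empty(self):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        assert not estimate_tissue_mask(img).any()

    def test_jaccard_with_ground_truth(self, small_sample):
        img, truth = small_sample
        est = estimate_tissue_mask(img)
        jac = (est & truth.tissue_mask).sum() / (est | truth.tissue_mask).sum()
        assert jac >= 0.95

    def test_invariant_to_added_dab(self):
        base = small(dab_target_fraction=0.0, seed=21)
        with_dab = small(dab_target_fraction=0.3, seed=21)
        m0 = estimate_tissue_mask(generate_sample(base)[0])
        m1 = estimate_tissue_mask(generate_sample(with_dab)[0])
        assert np.array_equal(m0, m1)


class TestQuantifyImage:
    def test_noise_free_fraction_recovery(self):
        img, truth = generate_sample(small(dab_target_fraction=0.4, seed=2))
        metrics, _, _ = quantify_image(img)
        assert abs(metrics.dab_area_fraction - 0.40) <= 0.02

    def test_metrics_translation_invariant(self):
        img, _ = generate_sample(
            small(tissue_radius_fraction=0.55, dab_target_fraction=0.2, seed=8)
        )
        shifted = np.roll(img, (15, -20), axis=(0, 1))
        a, _, _ = quantify_image(img)
        b, _, _ = quantify_image(shifted)
        assert a.dab_area_fraction == pytest.approx(b.dab_area_fraction, abs=1e-12)
        assert a.particle_count == b.particle_count
        assert a.integrated_dab_od == pytest.approx(b.integrated_dab_od, rel=1e-9)

    def test_blank_image_rejected(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.raises(EmptyTissueError):
            quantify_image(img)

    def test_measured_ladder_monotone(self):
        fracs = []
        for f in (0.05, 0.1, 0.2, 0.4):
            img, _ = generate_sample(small(dab_target_fraction=f, noise_sd=5.0, seed=13))
            fracs.append(quantify_image(img)[0].dab_area_fraction)
        assert all(a < b for a, b in zip(fracs, fracs[1:]))
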