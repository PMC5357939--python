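import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heprofiler import synth
from heprofiler.preprocess import (
    DegenerateHistogramError,
    PreprocessConfig,
    ReferenceHistogram,
    compute_reference_histogram,
    match_histogram,
    otsu_threshold,
    segment_effective_tissue,
)
from oracles import otsu_bruteforce


class TestReferenceHistogram:
    def test_mean_of_identical_images_is_their_histogram(self, rng):
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        ref = compute_reference_histogram([img, img.copy()])
        single = compute_reference_histogram([img])
        assert np.allclose(ref.histograms, single.histograms)
        assert ref.n_source_images == 2

    def test_uniform_gray_gives_step_cdf(self):
        img = np.full((16, 16, 3), 128, dtype=np.uint8)
        ref = compute_reference_histogram([img])
        cdfs = ref.cdfs
        assert np.all(cdfs[:, :128] == 0)
        assert np.all(cdfs[:, 128:] == 1)

    def test_mean_histogram_matches_binwise_oracle(self, small_cohort):
        imgs = [s.rgb for s in small_cohort[:5]]
        ref = compute_reference_histogram(imgs)
        for c in range(3):
            acc = np.zeros(256)
            for img in imgs:
                h = np.zeros(256)
                for v in img[..., c].ravel():  # explicit bin-count oracle
                    h[v] += 1
                acc += h / h.sum()
            assert np.allclose(ref.histograms[c], acc / len(imgs))

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            compute_reference_histogram([])

    def test_json_roundtrip(self, tmp_path, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        ref = compute_reference_histogram([img])
        ref.save(tmp_path / "ref.json")
        back = ReferenceHistogram.load(tmp_path / "ref.json")
        assert np.allclose(back.histograms, ref.histograms)


class TestMatchHistogram:
    def test_identity_when_histogram_equals_reference(self, rng):
        img = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        ref = compute_reference_histogram([img])
        out = match_histogram(img, ref)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    def test_constant_image_stays_constant(self, rng):
        ref = compute_reference_histogram(
            [rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)]
        )
        img = np.full((16, 16, 3), 77, dtype=np.uint8)
        out = match_histogram(img, ref)
        for c in range(3):
            assert len(np.unique(out[..., c])) == 1

    def test_reduces_cohort_intensity_variance(self, small_cohort):
        cohort = small_cohort[:10]
        ref = compute_reference_histogram(
            [s.rgb for s in cohort], [s.roi_mask for s in cohort]
        )
        pre = [s.rgb[s.roi_mask].mean() for s in cohort]
        post = [
            match_histogram(s.rgb, ref, s.roi_mask)[s.roi_mask].mean() for s in cohort
        ]
        assert np.var(post) < np.var(pre)

    def test_idempotent_up_to_quantization(self, small_cohort):
        s = small_cohort[0]
        ref = compute_reference_histogram(
            [x.rgb for x in small_cohort], [x.roi_mask for x in small_cohort]
        )
        once = match_histogram(s.rgb, ref, s.roi_mask)
        twice = match_histogram(once, ref, s.roi_mask)
        assert np.abs(twice.astype(int) - once.astype(int)).max() <= 1

    def test_pixels_outside_roi_untouched(self, small_cohort):
        s = small_cohort[0]
        ref = compute_reference_histogram([s.rgb], [s.roi_mask])
        out = match_histogram(s.rgb, ref, s.roi_mask)
        assert np.array_equal(out[~s.roi_mask], s.rgb[~s.roi_mask])


class TestOtsu:
    def test_symmetric_bimodal_splits_evenly(self):
        vals = np.array([0] * 50 + [255] * 50, dtype=np.uint8).reshape(10, 10)
        t = otsu_threshold(vals)
        assert 0 <= t < 255
        assert (vals <= t).sum() == 50

    def test_matches_bruteforce_on_random_images(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            assert otsu_threshold(img) == otsu_bruteforce(img)

    def test_bimodal_gaussians_threshold_between_modes(self, rng):
        vals = np.concatenate(
            [rng.normal(60, 5, 500), rng.normal(200, 5, 500)]
        )
        img = np.clip(vals, 0, 255).astype(np.uint8).reshape(-1, 50)
        assert 60 < otsu_threshold(img) < 200

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((8, 8), 3, dtype=np.uint8))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bruteforce_equality_property(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(np.uint8)
        if img.max() == img.min():
            return
        assert otsu_threshold(img) == otsu_bruteforce(img)


class TestTissueSegmentation:
    def test_dice_against_ground_truth(self):
        dices = []
        for seed in range(10):
            p = synth.class_params("epithelial", seed=seed, lumen_fraction=0.3)
            s = synth.render_he(synth.generate_layout(p), p)
            mask = segment_effective_tissue(s.rgb, s.roi_mask)
            inter = (mask & s.truth_tissue_mask).sum()
            dices.append(2 * inter / (mask.sum() + s.truth_tissue_mask.sum()))
        assert np.mean(dices) >= 0.90

    def test_all_white_roi_gives_near_empty_mask(self, rng):
        rgb = np.clip(
            rng.normal(253, 1.5, (128, 128, 3)), 0, 255
        ).astype(np.uint8)
        roi = np.ones((128, 128), dtype=bool)
        mask = segment_effective_tissue(rgb, roi)
        assert mask.sum() < 0.01 * roi.sum()

    def test_mask_subset_of_roi(self, epithelial_sample):
        s = epithelial_sample
        mask = segment_effective_tissue(s.rgb, s.roi_mask)
        assert not np.any(mask & ~s.roi_mask)

    def test_rotation_equivariance(self, epithelial_sample):
        s = epithelial_sample
        a = np.rot90(segment_effective_tissue(s.rgb, s.roi_mask))
        b = segment_effective_tissue(
            np.rot90(s.rgb).copy(), np.rot90(s.roi_mask).copy()
        )
        assert np.array_equal(a, b)

    def test_degenerate_input_returns_full_roi_with_warning(self):
        rgb = np.full((128, 128, 3), 200, dtype=np.uint8)
        roi = np.ones((128, 128), dtype=bool)
        with pytest.warns(UserWarning):
            mask = segment_effective_tissue(rgb, roi)
        assert np.array_equal(mask, roi)
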