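import numpy as np
import pytest

from heprofiler import synth
from heprofiler.features import (
    N_FEATURES,
    FEATURE_NAMES,
    catalogue_dataframe,
    density_features,
    extract_features,
    feature_catalogue,
    glcm_stats,
    lbp_histogram,
    mser_region_stats,
    nuclei_angle_features,
    nuclei_distance_features,
    sift_block_features,
)
from heprofiler.features.texture import (
    GLCM_OFFSET_ANGLES,
    dense_sift,
    lbp_code_image,
    quantize_levels,
)
from heprofiler.nuclei import NucleusSet, Nucleus, location_map
from oracles import (
    distance_features_bruteforce,
    glcm_bruteforce,
    glcm_props_bruteforce,
    lbp_code_bruteforce,
)


def _nucleus_set(points, areas=None, shape=(256, 256)):
    areas = areas or [150] * len(points)
    return NucleusSet(
        nuclei=[Nucleus(i, tuple(map(float, p)), a) for i, (p, a) in enumerate(zip(points, areas))],
        image_shape=shape,
    )


class TestCatalogue:
    def test_fixed_length_and_unique_names(self):
        cat = feature_catalogue()
        assert len(cat) == 241
        assert len({e.name for e in cat}) == 241
        assert FEATURE_NAMES == [e.name for e in cat]

    def test_multi_scale_naming_scheme_present(self):
        names = set(FEATURE_NAMES)
        for required in [
            "Contrast-H", "NhoodContrast-H", "ROI-BlockContrast-H",
            "mROI-BlockContrast-H", "ROIContrast-H", "Contrast-E",
            "LBP4H", "DensityLBP6", "NhoodMaxDist", "NhoodStdDist",
            "NhoodSkewness", "meanNucSize", "meanNucDistInNucNB",
            "NhoodMeanDist", "numberOfNucInNucNB", "NhoodNucAngleSkewABS",
            "NhoodNucAngleKurtABS", "NhoodNucAngleVar", "NhoodNucAngleStd0",
        ]:
            assert required in names, required

    def test_machine_readable_export(self):
        df = catalogue_dataframe()
        assert len(df) == 241
        assert set(df.columns) >= {"name", "extractor_id", "neighborhood_id", "channel_id"}


class TestGlcm:
    def test_constant_block(self):
        st = glcm_stats(np.full((8, 8), 100, dtype=np.uint8))
        assert st["Contrast"] == 0.0
        assert st["Energy"] == pytest.approx(1.0)
        assert st["Correlation"] == pytest.approx(1.0)
        assert st["MeanInt"] == 100.0

    def test_checkerboard_single_offset_contrast_one(self):
        """Adjacent levels always differ by 1 for offset (0,1) on a
        two-level checkerboard."""
        board = np.indices((8, 8)).sum(axis=0) % 2 * 16  # quantizes to levels 0, 1
        st = glcm_stats(board.astype(np.uint8), levels=16, angles=[0.0])
        assert st["Contrast"] == pytest.approx(1.0)
        assert st["Energy"] == pytest.approx(0.5)

    def test_matches_bruteforce_pair_counting(self, rng):
        offsets = [(0, 1), (1, 1), (1, 0), (1, -1)]
        for _ in range(3):
            block = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            st = glcm_stats(block, levels=16)
            mats = glcm_bruteforce(quantize_levels(block, 16), offsets, 16)
            expected = {k: [] for k in ("Contrast", "Energy", "Homogeneity", "Correlation")}
            for k in range(len(offsets)):
                props = glcm_props_bruteforce(mats[:, :, k])
                for key in expected:
                    expected[key].append(props[key])
            for key in expected:
                assert st[key] == pytest.approx(np.mean(expected[key]), rel=1e-9)

    def test_too_small_block_is_missing(self):
        assert glcm_stats(np.ones((1, 5), dtype=np.uint8)) is None


class TestLbp:
    def test_constant_block_all_mass_in_all_ones_bin(self):
        hist = lbp_histogram(np.full((16, 16), 50, dtype=np.uint8))
        assert hist[8] == pytest.approx(1.0)  # code P = all neighbors >= center

    def test_histogram_sums_to_one(self, rng):
        for _ in range(5):
            hist = lbp_histogram(rng.integers(0, 256, (12, 12)).astype(np.uint8))
            assert hist.sum() == pytest.approx(1.0)

    def test_codes_match_bruteforce_interior(self, rng):
        block = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        codes = lbp_code_image(block, 8, 1.0)
        for r in range(2, 30, 5):
            for c in range(2, 30, 7):
                assert codes[r, c] == lbp_code_bruteforce(block, r, c, 8, 1.0)

    def test_too_small_block_is_missing(self):
        assert lbp_histogram(np.ones((3, 3), dtype=np.uint8)) is None


class TestSift:
    def test_constant_block_zero_energy(self):
        st = sift_block_features(np.full((32, 32), 120, dtype=np.uint8))
        assert all(v == 0.0 for k, v in st.items() if k.endswith("_mean"))

    def test_rotation_preserves_total_energy(self, rng):
        block = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        a = dense_sift(block).band_energy.sum()
        b = dense_sift(np.rot90(block).copy()).band_energy.sum()
        assert b == pytest.approx(a, rel=0.01)

    def test_output_shape_contract(self, rng):
        st = sift_block_features(rng.integers(0, 256, (35, 35)).astype(np.uint8))
        assert len(st) == 16  # 8 band means + 8 band sds
        too_small = sift_block_features(np.ones((8, 8), dtype=np.uint8))
        assert too_small is None


class TestMserStats:
    def test_empty_list_zero_count(self):
        st = mser_region_stats([], (64, 64))
        assert st["MSERCount"] == 0.0

    def test_mean_area_arithmetic(self):
        from heprofiler.mser import CandidateRegion

        regs = [
            CandidateRegion(np.arange(a), a, (0, 0, 1, 1), (0.0, 0.0), 1.0, 0.1, 10)
            for a in (100, 300)
        ]
        st = mser_region_stats(regs, (64, 64))
        assert st["MSERMeanArea"] == 200.0

    def test_single_radius_render_low_area_spread(self, processed_epithelial):
        st = mser_region_stats(
            processed_epithelial.candidates, (256, 256)
        )
        assert st["MSERStdArea"] < 0.5 * st["MSERMeanArea"]


class TestDistanceFeatures:
    def test_single_pair_thirty_pixels(self):
        ns = _nucleus_set([(100, 100), (100, 130)])
        vals, miss = nuclei_distance_features(ns)
        assert vals["NhoodMeanDist"] == pytest.approx(30.0)
        assert vals["NhoodMaxDist"] == pytest.approx(30.0)
        assert vals["NhoodStdDist"] == pytest.approx(0.0)
        assert not miss["NhoodMeanDist"]

    def test_no_neighbors_zero_count_missing_distances(self):
        ns = _nucleus_set([(30, 30), (200, 200)])  # farther than the window
        vals, miss = nuclei_distance_features(ns)
        assert vals["numberOfNucInNucNB"] == 0.0
        assert miss["NhoodMeanDist"]

    def test_matches_allpairs_bruteforce(self, rng):
        pts = rng.uniform(20, 236, (50, 2))
        areas = list(rng.integers(80, 300, 50))
        ns = _nucleus_set(list(map(tuple, pts)), areas)
        vals, _ = nuclei_distance_features(ns)
        expected = distance_features_bruteforce(pts, np.asarray(areas, float))
        for key, exp in expected.items():
            if np.isnan(exp):
                continue
            assert vals[key] == pytest.approx(exp, rel=1e-9), key


class TestAngleFeatures:
    def test_collinear_one_direction_zero_variance(self):
        # chain along a row: every neighbor lies on the same axis
        ns = _nucleus_set([(100, 80), (100, 110), (100, 140)])
        vals, miss = nuclei_angle_features(ns)
        assert vals["NhoodNucAngleVar"] == pytest.approx(0.0, abs=1e-12)
        assert not miss["NhoodNucAngleVar"]

    def test_four_point_uniform_dispersion(self):
        """A nucleus whose neighbors sit at angles 0, pi/2, pi, 3pi/2 has
        circular variance 1 (restricting to the center's window only)."""
        center = [(128, 128)]
        outer = [(128, 168), (88, 128), (128, 88), (168, 128)]
        ns = _nucleus_set(center + outer)
        from heprofiler.features.distribution import _neighbor_offsets
        from heprofiler import circstats

        off = _neighbor_offsets(ns.centroids, 0, 50.0)
        theta = np.arctan2(off[:, 0], off[:, 1])
        assert circstats.circ_var(2.0 * theta) == pytest.approx(1.0, abs=1e-12)

    def test_epithelial_lower_dispersion_than_neoplastic(self):
        """Ordered rings present neighbors along the local row axis; the
        scattered class in all directions."""
        epi_vals, neo_vals = [], []
        for seed in range(10):
            for cls, acc in (("epithelial", epi_vals), ("neoplastic", neo_vals)):
                p = synth.class_params(cls, seed=seed)
                lay = synth.generate_layout(p)
                ns = _nucleus_set(list(map(tuple, lay.centers)))
                vals, _ = nuclei_angle_features(ns)
                acc.append(vals["NhoodNucAngleVar"])
        assert np.mean(epi_vals) < np.mean(neo_vals)
        assert np.max(epi_vals) < np.min(neo_vals)  # fully separated at defaults

    def test_variance_bounded(self, rng):
        pts = rng.uniform(30, 220, (30, 2))
        vals, _ = nuclei_angle_features(_nucleus_set(list(map(tuple, pts))))
        assert 0.0 <= vals["NhoodNucAngleVar"] <= 1.0
        assert vals["NhoodNucAngleStd"] >= 0.0


class TestDensityFeatures:
    def test_empty_map_zeros_flagged(self):
        ns = _nucleus_set([])
        vals, miss = density_features(location_map(ns))
        assert vals["DensityMean"] == 0.0
        assert all(miss.values())

    def test_kernel_mass_conservation(self):
        ns = _nucleus_set([(100, 100), (150, 150), (128, 60)])
        vals, _ = density_features(location_map(ns))
        lm = location_map(ns)
        from scipy.ndimage import gaussian_filter

        density = gaussian_filter(lm.counts.astype(float), 8.0, mode="constant")
        assert density.sum() == pytest.approx(3.0, rel=0.01)

    def test_doubling_count_doubles_mean_density(self):
        p1 = synth.class_params("neoplastic", seed=5, n_nuclei=30)
        p2 = synth.class_params("neoplastic", seed=5, n_nuclei=60)
        means = []
        for p in (p1, p2):
            lay = synth.generate_layout(p)
            ns = _nucleus_set(list(map(tuple, lay.centers)))
            vals, _ = density_features(location_map(ns))
            means.append(vals["DensityMean"])
        assert means[1] == pytest.approx(2 * means[0], rel=0.15)

    def test_density_lbp_histogram_sums_to_one(self, processed_epithelial):
        fv = processed_epithelial.features.to_series()
        total = sum(fv[f"DensityLBP{k}"] for k in range(1, 11))
        assert total == pytest.approx(1.0)


class TestExtract:
    def test_vector_length_and_order(self, processed_epithelial):
        fv = processed_epithelial.features
        assert len(fv.values) == N_FEATURES
        assert fv.names == FEATURE_NAMES

    def test_deterministic(self, processed_epithelial, epithelial_sample):
        from heprofiler.pipeline import process_sample

        again = process_sample(
            epithelial_sample.rgb, epithelial_sample.roi_mask, sample_id="epi3"
        )
        assert np.array_equal(
            again.features.values, processed_epithelial.features.values
        )

    def test_zero_nuclei_flags_nucleus_anchored_features(self):
        p = synth.SceneParams(arrangement_class="epithelial", n_nuclei=0, seed=0)
        s = synth.render_he(synth.generate_layout(p), p)
        from heprofiler.pipeline import process_sample

        prod = process_sample(s.rgb, s.roi_mask)
        assert len(prod.nuclei) == 0
        fv = prod.features
        by_name = dict(zip(fv.names, fv.missing))
        assert by_name["NhoodContrast-H"]
        assert by_name["NhoodMeanDist"]
        assert not by_name["ROIContrast-H"]  # ROI-level features still computed
        assert not by_name["ROI-BlockContrast-H"]

    def test_mirror_invariance_of_symmetric_features(self, processed_epithelial):
        """Reflection-invariant families (GLCM, riu2 LBP, distances,
        orientation dispersion, density) agree on the mirrored sample."""
        prod = processed_epithelial
        W = prod.stains.shape[1]
        flip = lambda a: np.ascontiguousarray(a[:, ::-1])
        from heprofiler.stains import StainChannels

        stains_m = StainChannels(
            hematoxylin=flip(prod.stains.hematoxylin),
            eosin=flip(prod.stains.eosin),
            residual=flip(prod.stains.residual),
        )
        nuclei_m = NucleusSet(
            nuclei=[
                Nucleus(
                    n.nucleus_id,
                    (n.centroid[0], W - 1 - n.centroid[1]),
                    n.area,
                    pixels=(
                        None if n.pixels is None
                        else (n.pixels // W) * W + (W - 1 - n.pixels % W)
                    ),
                )
                for n in prod.nuclei.nuclei
            ],
            image_shape=prod.nuclei.image_shape,
        )
        cands_m = None  # MSER summaries tested for count/area via nuclei path
        fv_m = extract_features(
            stains_m,
            flip(np.ones_like(prod.tissue_mask)),  # roi: full frame both ways
            flip(prod.tissue_mask),
            nuclei_m,
            prod.candidates,  # areas/stabilities are mirror-invariant scalars
            config=None,
        )
        fv = extract_features(
            prod.stains,
            np.ones_like(prod.tissue_mask),
            prod.tissue_mask,
            prod.nuclei,
            prod.candidates,
        )
        a = fv.to_series()
        b = fv_m.to_series()
        invariant = (
            [f"{p}{s}-{c}" for p in ("", "Nhood", "ROI") for s in ("MeanInt", "Contrast", "Energy", "Homogeneity", "Correlation") for c in ("H", "E")]
            + [f"{p}LBP{k}{c}" for p in ("", "Nhood", "ROI") for k in range(1, 11) for c in ("H", "E")]
            + ["NhoodMeanDist", "NhoodMaxDist", "NhoodStdDist", "NhoodSkewness",
               "meanNucDistInNucNB", "numberOfNucInNucNB", "meanNucSize",
               "NhoodNucAngleR", "NhoodNucAngleVar", "NhoodNucAngleStd",
               "NhoodNucAngleStd0", "NhoodNucAngleKurt",
               "NhoodNucAngleVarABS", "NhoodNucAngleStd0ABS", "NhoodNucAngleKurtABS"]
        )
        for name in invariant:
            assert a[name] == pytest.approx(b[name], abs=1e-6), name

    def test_class_sensitivity_on_cohort(self, small_cohort):
        """At the study conditions, many catalogue features separate the
        two arrangement classes strongly."""
        from heprofiler.pipeline import cohort_features

        X, y = cohort_features(small_cohort)
        A = X[(y == "epithelial").to_numpy()].to_numpy()
        B = X[(y == "neoplastic").to_numpy()].to_numpy()
        with np.errstate(all="ignore"):
            smd = np.abs(A.mean(0) - B.mean(0)) / np.sqrt((A.var(0) + B.var(0)) / 2)
        assert np.nansum(smd > 1) >= 10
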