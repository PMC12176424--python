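"""Texture matrices vs brute-force oracles; feature formulas; symmetry suite."""

import numpy as np
import pytest

import oracles
from conjradiomics.image_prep import QuantizedRoi, quantize_gray_levels
from conjradiomics.texture import (
    ExtractionConfig,
    compute_glcm,
    compute_gldm,
    compute_glrlm,
    compute_glszm,
    extract_feature_vector,
    first_order_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
)


def _q(levels, mask, ng):
    return QuantizedRoi(levels=np.asarray(levels, dtype=np.int32),
                        mask=np.asarray(mask, dtype=bool), ng=ng,
                        bin_edges=np.linspace(0, 1, ng + 1))


def _random_cases(n, seed=42):
    rng = np.random.default_rng(seed)
    return [oracles.random_quantized(rng) for _ in range(n)]


class TestMatrixOracles:
    """Exact integer equality against brute-force enumeration on random
    16x16 level maps with Ng=8 and random masks."""

    @pytest.mark.parametrize("case", range(50))
    def test_all_families_match_oracles(self, case):
        rng = np.random.default_rng(1000 + case)
        levels, mask = oracles.random_quantized(rng)
        q = _q(levels, mask, 8)
        assert np.array_equal(compute_glcm(q).counts,
                              oracles.glcm_pairs(levels, mask, 8))
        assert np.array_equal(compute_glrlm(q).counts[:, :, :16],
                              oracles.glrlm_runs(levels, mask, 8))
        got_szm = compute_glszm(q).counts
        exp_szm = oracles.glszm_zones(levels, mask, 8)
        ns = max(got_szm.shape[1], exp_szm.shape[1])
        assert np.array_equal(np.pad(got_szm, ((0, 0), (0, ns - got_szm.shape[1]))),
                              np.pad(exp_szm, ((0, 0), (0, ns - exp_szm.shape[1]))))
        got_dm = compute_gldm(q).counts
        exp_dm = oracles.gldm_dependences(levels, mask, 8)
        nd = max(got_dm.shape[1], exp_dm.shape[1])
        assert np.array_equal(np.pad(got_dm, ((0, 0), (0, nd - got_dm.shape[1]))),
                              np.pad(exp_dm, ((0, 0), (0, nd - exp_dm.shape[1]))))

    @pytest.mark.parametrize("case", range(10))
    def test_features_match_direct_formulas(self, case):
        """Every feature value equals a naive loop-based evaluation of its
        formula on the oracle's matrix, to 1e-10 relative."""
        rng = np.random.default_rng(2000 + case)
        levels, mask = oracles.random_quantized(rng)
        q = _q(levels, mask, 8)

        got = glcm_features(compute_glcm(q))
        exp = oracles.glcm_features_direct(oracles.glcm_pairs(levels, mask, 8))
        assert set(got) == set(exp)
        for k in exp:
            assert got[k] == pytest.approx(exp[k], rel=1e-10, abs=1e-10), k

        got = glrlm_features(compute_glrlm(q))
        exp = oracles.glrlm_features_direct(oracles.glrlm_runs(levels, mask, 8))
        for k in exp:
            assert got[k] == pytest.approx(exp[k], rel=1e-10, abs=1e-10), k

        m = compute_glszm(q)
        got = glszm_features(m)
        exp = oracles.glszm_features_direct(
            oracles.glszm_zones(levels, mask, 8), int(mask.sum()))
        for k in exp:
            assert got[k] == pytest.approx(exp[k], rel=1e-10, abs=1e-10), k

        got = gldm_features(compute_gldm(q))
        exp = oracles.gldm_features_direct(
            oracles.gldm_dependences(levels, mask, 8))
        for k in exp:
            assert got[k] == pytest.approx(exp[k], rel=1e-10, abs=1e-10), k


class TestGlcmBasics:
    def test_uniform_2x2_distance1_counts(self):
        q = _q(np.ones((2, 2)), np.ones((2, 2)), 2)
        m = compute_glcm(q, distance=1)
        assert m.counts[0, 0, 0] == 4  # 0 deg: two pairs, both orders
        assert m.counts[0].sum() == 4

    def test_symmetry_per_angle(self, rng):
        levels, mask = oracles.random_quantized(rng)
        m = compute_glcm(_q(levels, mask, 8))
        for a in range(4):
            assert np.array_equal(m.counts[a], m.counts[a].T)

    def test_totals_equal_twice_pair_count(self):
        """Matrix totals = 2x the number of in-mask neighbor pairs."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            levels, mask = oracles.random_quantized(rng)
            m = compute_glcm(_q(levels, mask, 8))
            oracle = oracles.glcm_pairs(levels, mask, 8)
            for a in range(4):
                assert m.counts[a].sum() == oracle[a].sum()
                assert m.counts[a].sum() % 2 == 0

    def test_checkerboard_correlation_minus_one(self):
        cb = (np.indices((4, 4)).sum(axis=0) % 2) + 1
        m = compute_glcm(_q(cb, np.ones((4, 4)), 2))
        # angles 0 (index 0) and 90 (index 2): all pairs are (1,2)/(2,1)
        for a in (0, 2):
            p = m.counts[a] / m.counts[a].sum()
            i = np.array([1.0, 2.0])
            px = p.sum(axis=1)
            ux = (i * px).sum()
            sx = np.sqrt((((i - ux) ** 2) * px).sum())
            corr = ((p * np.outer(i - ux, i - ux)).sum()) / sx**2
            assert corr == pytest.approx(-1.0, abs=1e-12)


class TestDegenerateConventions:
    def test_constant_roi_glcm_conventions(self):
        q = _q(np.ones((4, 4)), np.ones((4, 4)), 8)
        f = glcm_features(compute_glcm(q))
        assert f["Imc2"] == 0.0
        assert f["Correlation"] == 1.0

    def test_constant_row_glrlm(self):
        lv = np.ones((1, 5))
        f = glrlm_features(compute_glrlm(_q(lv, np.ones((1, 5)), 4)))
        # single run of length 5 at 0 deg; vertical/diagonal directions have
        # 5 runs of length 1 each
        m = compute_glrlm(_q(lv, np.ones((1, 5)), 4))
        assert m.counts[0, 0, 4] == 1  # 0 deg: one run of length 5
        assert m.counts[2, 0, 0] == 5  # 90 deg: five runs of length 1
        assert f["RunLengthNonUniformityNormalized"] <= 1.0

    def test_single_row_runs(self):
        lv = np.array([[1, 1, 2]])
        m = compute_glrlm(_q(lv, np.ones((1, 3)), 2))
        assert m.counts[0, 0, 1] == 1  # level 1, length 2
        assert m.counts[0, 1, 0] == 1  # level 2, length 1
        assert m.counts[0].sum() == 2

    def test_constant_single_row_sre(self):
        n = 6
        m = compute_glrlm(_q(np.ones((1, n)), np.ones((1, n)), 2))
        # at 0 deg: single run of length n -> SRE = 1/n^2
        p = m.counts[0] / m.counts[0].sum()
        j = np.arange(1, m.counts[0].shape[1] + 1)
        assert (p / j**2).sum() == pytest.approx(1 / n**2)

    def test_constant_roi_rlnn_is_one(self):
        f = glrlm_features(compute_glrlm(_q(np.ones((1, 4)), np.ones((1, 4)), 2)))
        # all runs share one gray level -> GLNN = 1 in every direction
        assert f["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)

    def test_constant_roi_glszm_single_zone(self):
        np_pix = 12
        q = _q(np.ones((3, 4)), np.ones((3, 4)), 4)
        m = compute_glszm(q)
        assert m.counts.sum() == 1
        f = glszm_features(m)
        assert f["ZonePercentage"] == pytest.approx(1 / np_pix)
        assert f["ZoneVariance"] == pytest.approx(0.0)

    def test_checkerboard_glszm_merges_diagonals(self):
        """With 8-connectivity, same-level diagonal neighbors merge: a
        two-level checkerboard forms exactly two zones (the oracle flood
        fill decides the expected value)."""
        cb = (np.indices((4, 4)).sum(axis=0) % 2) + 1
        mask = np.ones((4, 4), bool)
        exp = oracles.glszm_zones(cb, mask, 2)
        m = compute_glszm(_q(cb, mask, 2))
        assert m.counts.sum() == exp.sum() == 2  # one zone per level

    def test_constant_3x3_gldm_dependences(self):
        q = _q(np.ones((3, 3)), np.ones((3, 3)), 4)
        m = compute_gldm(q, alpha=0)
        # center 8, edges 5, corners 3
        assert m.counts[0, 8] == 1
        assert m.counts[0, 5] == 4
        assert m.counts[0, 3] == 4
        assert m.counts.sum() == 9

    def test_constant_roi_gldm_gln_equals_nz(self):
        q = _q(np.ones((4, 5)), np.ones((4, 5)), 4)
        f = gldm_features(compute_gldm(q))
        assert f["GrayLevelNonUniformity"] == pytest.approx(20.0)

    def test_dnn_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            levels, mask = oracles.random_quantized(rng)
            f = gldm_features(compute_gldm(_q(levels, mask, 8)))
            assert 0 < f["DependenceNonUniformityNormalized"] <= 1

    def test_constant_roi_first_order(self):
        f = first_order_features(np.full((4, 4), 7.0), np.ones((4, 4), bool))
        assert f["Variance"] == 0.0
        assert f["InterquartileRange"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0


class TestFirstOrder:
    def test_small_roi_percentile_convention(self):
        img = np.array([[1.0, 2.0, 3.0, 4.0]])
        f = first_order_features(img, np.ones((1, 4), bool))
        assert f["Maximum"] == 4.0
        # linear-interpolation percentiles: P25 = 1.75, P75 = 3.25
        assert f["InterquartileRange"] == pytest.approx(1.5)

    def test_mirror_invariance(self, rng):
        img = rng.random((8, 8)) * 255
        mask = np.ones((8, 8), bool)
        f1 = first_order_features(img, mask)
        f2 = first_order_features(np.fliplr(img), mask)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12)


class TestExtraction:
    def test_inventory_size_matches_config(self, small_cohort):
        _, parts, photos = small_cohort
        cfg = ExtractionConfig()
        fv = extract_feature_vector(photos[0], cfg)
        n_images = len(cfg.image_types())  # original + 3 LoG + 2 wavelet = 6
        assert n_images == 6
        families = {name.split("|")[1] for name in fv}
        assert families == {"FirstOrder", "GLCM", "GLRLM", "GLSZM", "GLDM"}
        per_image = len(fv) / n_images
        assert len(fv) == per_image * n_images  # balanced inventory
        assert not any("Shape" in k for k in fv)

    def test_determinism(self, small_cohort):
        _, parts, photos = small_cohort
        f1 = extract_feature_vector(photos[0])
        f2 = extract_feature_vector(photos[0])
        assert f1 == f2

    def test_original_features_ignore_out_of_mask_pixels(self, small_cohort):
        _, parts, photos = small_cohort
        ph = photos[0]
        cfg = ExtractionConfig(include_original=True, log_sigmas=(),
                               wavelet_subbands=())
        base = extract_feature_vector(ph, cfg)
        img = ph.image.copy()
        out_pix = np.argwhere(~ph.mask)
        img[tuple(out_pix[0])] = 255 - img[tuple(out_pix[0])]
        modified = extract_feature_vector((img, ph.mask), cfg)
        assert base == modified

    def test_rotation_invariance_of_aggregated_features(self, small_cohort):
        """Angle-averaged GLCM/GLRLM and orientation-free GLSZM/GLDM/
        first-order features are invariant under a 90-degree rotation of
        image and mask."""
        _, parts, photos = small_cohort
        ph = photos[0]
        cfg = ExtractionConfig(include_original=True, log_sigmas=(),
                               wavelet_subbands=())
        f1 = extract_feature_vector((ph.image, ph.mask), cfg)
        f2 = extract_feature_vector((np.rot90(ph.image), np.rot90(ph.mask)), cfg)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-10, rel=1e-10), k

    def test_empty_family_recorded_as_missing(self):
        # 1-pixel ROI: GLCM has no pairs -> family features missing, logged
        img = np.zeros((12, 12))
        mask = np.zeros((12, 12), bool)
        mask[5, 5] = True
        errs = []
        fv = extract_feature_vector((img, mask),
                                    ExtractionConfig(log_sigmas=(),
                                                     wavelet_subbands=()),
                                    errors=errs)
        assert errs  # cause was logged
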