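"""Feature bank: intensity stats, Haralick texture, enhancement filters,
segmentation, and vessel morphology."""

import math
import warnings

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from stenoselect.data import GrayImage
from stenoselect.features import (
    ENHANCEMENT_METHODS,
    FeatureVector,
    FilterBankSpec,
    catalog_size,
    enhance,
    extract_feature_vector,
    glcm_haralick,
    intensity_features,
    morphology_features,
    segment_vessels,
    skeleton_segments,
)
from stenoselect.synthetic import make_vessel_patch


class TestIntensity:
    def test_constant_image(self):
        fv = intensity_features(np.full((5, 5), 7))
        assert fv["Minimum Intensity"] == fv["Maximum Intensity"] == 7
        assert fv["Median Intensity"] == fv["Mean Intensity"] == 7
        assert fv["Variance Intensity"] == fv["Standard Deviation Intensity"] == 0

    def test_two_pixel_symmetry(self):
        fv = intensity_features(np.array([[0, 255]]))
        assert fv["Mean Intensity"] == 127.5
        assert fv["Minimum Intensity"] == 0 and fv["Maximum Intensity"] == 255

    def test_cross_check_against_numpy(self, rng):
        img = rng.integers(0, 256, (64, 64))
        fv = intensity_features(img)
        assert fv["Variance Intensity"] == pytest.approx(np.var(img))
        assert fv["Median Intensity"] == pytest.approx(np.median(img))


class TestHaralick:
    def test_constant_image_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fv = glcm_haralick(np.full((8, 8), 3), levels=8)
        assert fv["Angular Second Moment"] == 1.0
        assert fv["Entropy"] == 0.0
        assert fv["Contrast"] == 0.0

    def test_checkerboard_hand_computed(self):
        """2-level checkerboard, offset (0,1): the symmetric GLCM is
        [[0,.5],[.5,0]], so ASM = 1/2 and contrast is maximal (=1)."""
        board = (np.indices((8, 8)).sum(0) % 2) * 255
        fv = glcm_haralick(board, levels=2, offsets=[(0, 1)])
        assert fv["Angular Second Moment"] == pytest.approx(0.5)
        assert fv["Contrast"] == pytest.approx(1.0)

    def test_fourteen_statistics_with_sane_ranges(self, rng):
        img = rng.integers(0, 256, (32, 32))
        fv = glcm_haralick(img)
        assert len(fv) == 14
        assert fv["Entropy"] >= 0
        assert 0 < fv["Angular Second Moment"] <= 1
        assert 0 <= fv["Information Measure of Correlation 2"] <= 1
        assert 0 <= fv["Maximal Correlation Coefficient"] <= 1 + 1e-9


@pytest.fixture(scope="module")
def tube():
    img, centerline = make_vessel_patch(size=64, width=3.0, curvature=0.0,
                                        noise_sd=0.0, seed=0)
    return img, centerline


class TestEnhance:

    def test_frangi_ridge_contrast(self, tube):
        img, centerline = tube
        resp = enhance(img, "frangi")
        on = resp[centerline].mean()
        off = resp[~centerline].mean()
        assert on > 5 * max(off, 1e-12)

    def test_tophat_recovers_thin_tube_and_kills_constant(self, tube):
        img, centerline = tube
        resp = enhance(img, "tophat")
        assert resp[centerline].mean() > 10 * max(resp[~centerline].mean(), 1e-12)
        flat = GrayImage(np.full((32, 32), 90))
        assert np.allclose(enhance(flat, "tophat"), 0.0)

    def test_gabor_bank_rotation_invariance(self):
        img, _ = make_vessel_patch(size=64, width=4.0, curvature=0.0,
                                   noise_sd=0.0, seed=1)
        rot = GrayImage(np.rot90(img.pixels).copy())
        a = enhance(img, "gabor_multi")
        b = enhance(rot, "gabor_multi")
        # the orientation bank spans 180 degrees, so a 90-degree rotation
        # leaves the response distribution unchanged
        assert np.quantile(a, 0.99) == pytest.approx(np.quantile(b, 0.99), rel=0.05)

    @pytest.mark.parametrize("method", ENHANCEMENT_METHODS)
    def test_shape_preserving_and_deterministic(self, tube, method):
        img, _ = tube
        a = enhance(img, method)
        b = enhance(img, method)
        assert a.shape == img.pixels.shape
        np.testing.assert_array_equal(a, b)

    def test_unknown_method(self, tube):
        with pytest.raises(ValueError, match="unknown"):
            enhance(tube[0], "laplacian")


class TestSegment:
    def test_bimodal_response_recovers_planted_mask(self, rng):
        planted = np.zeros((64, 64), dtype=bool)
        rr, cc = draw_disk((32, 32), 12)
        planted[rr, cc] = True
        resp = np.where(planted, rng.normal(10, 0.5, planted.shape),
                        rng.normal(0, 0.5, planted.shape))
        mask = segment_vessels(resp)
        dice = 2 * (mask & planted).sum() / (mask.sum() + planted.sum())
        assert dice > 0.95

    def test_constant_response_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_vessels(np.zeros((8, 8)))
        assert not mask.any()

    def test_inverting_response_inverts_mask(self, rng):
        planted = np.zeros((32, 32), dtype=bool)
        planted[8:24, 8:24] = True
        resp = np.where(planted, 5.0, -5.0) + rng.normal(0, 0.1, planted.shape)
        m1 = segment_vessels(resp)
        m2 = segment_vessels(-resp)
        assert (m1 == ~m2).mean() > 0.99


class TestMorphology:
    def test_circle_circularity_and_identity(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = draw_disk((32, 32), 20)
        mask[rr, cc] = True
        fv = morphology_features(mask, mask.astype(float))
        assert fv["Maximum Circularity Ratio"] == pytest.approx(1.0, abs=0.1)
        assert fv["Maximum Compactness"] == pytest.approx(4 * math.pi, rel=0.1)
        # algebraic identity C * Rc = 4*pi, exact by construction
        assert fv["Maximum Compactness"] * fv["Maximum Circularity Ratio"] == pytest.approx(
            4 * math.pi, abs=1e-9
        )

    def test_square_compactness(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[4:36, 4:36] = True
        fv = morphology_features(mask, mask.astype(float))
        assert fv["Maximum Compactness"] == pytest.approx(16.0, rel=0.1)

    def test_rectangle_elongatedness_exact(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[3:5, 2:12] = True  # 10 x 2 filled rectangle
        fv = morphology_features(mask, mask.astype(float))
        assert fv["Maximum Elongatedness"] == pytest.approx(5.0, abs=1e-9)

    def test_empty_mask_sentinels_with_warning(self):
        with pytest.warns(UserWarning, match="empty vessel mask"):
            fv = morphology_features(np.zeros((8, 8), dtype=bool), np.zeros((8, 8)))
        assert fv["Number Of Vessel Segments"] == 0.0

    def test_hand_drawn_three_branch_skeleton(self):
        """A T-shaped skeleton: three branches of 5 pixels each (the junction
        pixel is shared), one arterial section."""
        t = np.zeros((12, 12), dtype=bool)
        t[5, 2:11] = True
        t[5:10, 6] = True
        segments = skeleton_segments(t)
        assert sorted(s.length for s in segments) == [5, 5, 5]
        assert {s.section for s in segments} == {1}

    def test_straight_line_single_segment(self):
        line = np.zeros((10, 10), dtype=bool)
        line[4, 1:9] = True
        segments = skeleton_segments(line)
        assert [s.length for s in segments] == [8]


class TestExtract:
    def test_deterministic_and_catalog_sized(self):
        img, _ = make_vessel_patch(seed=5)
        a = extract_feature_vector(img)
        b = extract_feature_vector(img)
        assert a.names == b.names
        np.testing.assert_array_equal(a.values, b.values)
        assert len(a) == catalog_size()

    def test_narrowing_shifts_some_morphology_feature(self):
        """At least one morphological feature separates narrowed from uniform
        tubes across paired patches (planted effect)."""
        diffs = []
        for seed in range(12):
            uni, _ = make_vessel_patch(width=7, narrowing=0.0, noise_sd=4.0, seed=seed)
            sten, _ = make_vessel_patch(width=7, narrowing=0.6, noise_sd=4.0, seed=seed)
            a = extract_feature_vector(uni)
            b = extract_feature_vector(sten)
            diffs.append(b.values - a.values)
        diffs = np.vstack(diffs)
        mean = diffs.mean(axis=0)
        sem = diffs.std(axis=0, ddof=1) / np.sqrt(diffs.shape[0]) + 1e-12
        t_stats = np.abs(mean) / sem
        assert (t_stats > 2).any()


def test_feature_vector_rejects_duplicates_and_nonfinite():
    fv = FeatureVector([("a", 1.0)])
    with pytest.raises(ValueError, match="duplicate"):
        fv.append("a", 2.0)
    with pytest.raises(ValueError, match="finite"):
        fv.append("b", float("nan"))
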