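"""Morphology against brute-force set-definition oracles, and cropping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from dentexture import (
    NoForegroundError,
    ParameterError,
    StructuringElement,
    binarize,
    dilate,
    erode,
    extract_front_face,
    find_contours,
    generate_tooth_image,
    opening,
)
from dentexture.synthetic import ClassTextureSpec


# --- independent oracles: literal set definitions, quadratic loops -------

def erode_oracle(a, se):
    h, w = a.shape
    mask, (ar, ac) = np.asarray(se.mask, dtype=bool), se.anchor
    out = np.zeros_like(a, dtype=bool)
    for r in range(h):
        for c in range(w):
            ok = True
            for i, j in zip(*np.nonzero(mask)):
                rr, cc = r + i - ar, c + j - ac
                if not (0 <= rr < h and 0 <= cc < w) or not a[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def dilate_oracle(a, se):
    h, w = a.shape
    mask, (ar, ac) = np.asarray(se.mask, dtype=bool), se.anchor
    out = np.zeros_like(a, dtype=bool)
    for r, c in zip(*np.nonzero(a)):
        for i, j in zip(*np.nonzero(mask)):
            rr, cc = r + i - ar, c + j - ac
            if 0 <= rr < h and 0 <= cc < w:
                out[rr, cc] = True
    return out


def random_se(rng, max_size=5):
    h, w = rng.integers(1, max_size + 1), rng.integers(1, max_size + 1)
    mask = rng.random((h, w)) < 0.6
    if not mask.any():
        mask[h // 2, w // 2] = True
    return StructuringElement(mask, (int(rng.integers(h)), int(rng.integers(w))))


class TestBinarize:
    def test_fixed_threshold_all_ones(self):
        out = binarize(np.full((4, 4), 0.9), "fixed", 0.5)
        assert out.all() and out.dtype == bool

    def test_otsu_two_level_image(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((20, 20)) < 0.4, 0.8, 0.2)
        out = binarize(img, "otsu")
        np.testing.assert_array_equal(out, img == 0.8)

    def test_constant_image_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="mid-range"):
            out = binarize(np.full((5, 5), 0.7))
        assert out.all()

    def test_invalid_fixed_value(self):
        with pytest.raises(ParameterError):
            binarize(np.zeros((3, 3)), "fixed", 1.5)


class TestMorphologyExamples:
    def test_single_pixel_erodes_away(self):
        img = np.zeros((7, 7), dtype=bool)
        img[3, 3] = True
        assert not erode(img, StructuringElement.square(3)).any()

    def test_erosion_of_block_is_interior(self):
        img = np.ones((5, 5), dtype=bool)
        out = erode(img, StructuringElement.square(3))
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:4, 1:4] = True
        np.testing.assert_array_equal(out, expected)

    def test_single_pixel_dilates_to_block(self):
        img = np.zeros((7, 7), dtype=bool)
        img[3, 3] = True
        out = dilate(img, StructuringElement.square(3))
        expected = np.zeros((7, 7), dtype=bool)
        expected[2:5, 2:5] = True
        np.testing.assert_array_equal(out, expected)

    def test_dilation_of_empty_is_empty(self):
        assert not dilate(np.zeros((6, 6), dtype=bool),
                          StructuringElement.square(3)).any()

    def test_empty_structuring_element_rejected(self):
        with pytest.raises(ParameterError):
            StructuringElement(np.zeros((3, 3), dtype=bool), (1, 1))


class TestMorphologyOracle:
    def test_agrees_with_set_definition_on_random_grids(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            a = rng.random((20, 20)) < rng.uniform(0.2, 0.6)
            se = random_se(rng)
            np.testing.assert_array_equal(erode(a, se), erode_oracle(a, se))
            np.testing.assert_array_equal(dilate(a, se), dilate_oracle(a, se))

    def test_agrees_with_scipy_on_centered_odd_kernels(self):
        rng = np.random.default_rng(7)
        for size in (3, 5):
            se = StructuringElement.square(size)
            a = rng.random((24, 24)) < 0.4
            np.testing.assert_array_equal(
                erode(a, se),
                ndimage.binary_erosion(a, np.ones((size, size)), border_value=0),
            )
            np.testing.assert_array_equal(
                dilate(a, se),
                ndimage.binary_dilation(a, np.ones((size, size)), border_value=0),
            )

    def test_erosion_composition_identity(self):
        # erode(erode(A,B),B) == erode(A, B plus B): for a centered 3x3
        # square element, B plus B is the centered 5x5 square
        rng = np.random.default_rng(5)
        se = StructuringElement.square(3)
        se_big = StructuringElement.square(5)
        for _ in range(20):
            a = rng.random((20, 20)) < 0.7
            np.testing.assert_array_equal(
                erode(erode(a, se), se), erode(a, se_big)
            )

    def test_duality_with_reflected_element(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.random((20, 20)) < 0.5
            se = random_se(rng)
            mask = np.asarray(se.mask, dtype=bool)
            refl = StructuringElement(
                mask[::-1, ::-1],
                (mask.shape[0] - 1 - se.anchor[0], mask.shape[1] - 1 - se.anchor[1]),
            )
            # duality holds away from the border; compare interior pixels only
            pad = max(mask.shape)
            inner = (slice(pad, -pad), slice(pad, -pad))
            np.testing.assert_array_equal(
                dilate(a, se)[inner], (~erode(~a, refl))[inner]
            )


@st.composite
def binary_grids(draw):
    h = draw(st.integers(6, 16))
    w = draw(st.integers(6, 16))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    return rng.random((h, w)) < draw(st.floats(0.2, 0.8))


class TestMorphologyProperties:
    @settings(max_examples=30, deadline=None)
    @given(binary_grids(), st.integers(1, 2))
    def test_anti_extensivity_and_extensivity(self, a, halfsize):
        se = StructuringElement.square(2 * halfsize + 1)  # anchor cell active
        er, di = erode(a, se), dilate(a, se)
        assert not (er & ~a).any()  # erode(A) subset of A
        assert not (a & ~di).any()  # A subset of dilate(A)

    @settings(max_examples=30, deadline=None)
    @given(binary_grids())
    def test_opening_is_idempotent(self, a):
        se = StructuringElement.square(3)
        once = opening(a, se)
        np.testing.assert_array_equal(opening(once, se), once)


class TestFindContours:
    def test_single_block(self):
        img = np.zeros((10, 10), dtype=bool)
        img[2:6, 3:7] = True
        regions = find_contours(img)
        assert len(regions) == 1
        assert regions[0].area == 16
        assert regions[0].bounding_box == (2, 3, 6, 7)

    def test_two_blocks_sorted_by_area(self):
        img = np.zeros((20, 20), dtype=bool)
        img[1:6, 1:6] = True  # 25
        img[10:13, 10:13] = True  # 9
        regions = find_contours(img)
        assert [r.area for r in regions] == [25, 9]

    def test_empty_image(self):
        assert find_contours(np.zeros((5, 5), dtype=bool)) == []

    def test_boundary_is_closed(self):
        img = np.zeros((8, 8), dtype=bool)
        img[2:5, 2:5] = True
        boundary = find_contours(img)[0].boundary
        np.testing.assert_allclose(boundary[0], boundary[-1])


class TestExtractFrontFace:
    def test_crop_matches_ground_truth_and_specks_removed(self):
        spec = ClassTextureSpec(2, 10.0, 40.0, ridge_contrast=0.5, noise_sd=0.03)
        rng = np.random.default_rng(21)
        img, mask = generate_tooth_image(spec, 128, rng, speck_count=10,
                                         return_mask=True)
        crop = extract_front_face(img, pad=2)
        rows = np.any(mask, axis=1).nonzero()[0]
        cols = np.any(mask, axis=0).nonzero()[0]
        th, tw = rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1
        # crop should track the tooth bounding box (opening can nibble edges)
        assert abs(crop.shape[0] - (th + 4)) <= 6
        assert abs(crop.shape[1] - (tw + 4)) <= 6
        assert not (crop > 0.9).any()  # no specks inside the selected region

    def test_full_foreground_returns_whole_image(self):
        img = np.full((32, 32), 0.8)
        img[0, 0] = 0.1  # break constancy so Otsu is defined
        crop = extract_front_face(img, se_size=3, pad=0)
        assert crop.shape == (32, 32)

    def test_all_background_raises(self):
        with pytest.raises(NoForegroundError):
            extract_front_face(np.zeros((40, 40)), se_size=10,
                               threshold_method="fixed", fixed_value=0.5)

    def test_opening_removes_all_specks_over_many_images(self):
        """The 10x10 opening must delete every planted speck in 50 images."""
        from dentexture.segmentation import opening as _opening, binarize as _bin

        spec = ClassTextureSpec(1, 12.0, 100.0, ridge_contrast=0.5, noise_sd=0.04)
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            img, mask = generate_tooth_image(spec, 128, rng, speck_count=8,
                                             return_mask=True)
            cleaned = _opening(_bin(img))
            specks = (img > 0.9) & ~mask
            assert specks.any()
            assert not (cleaned & specks).any()
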