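"""Spectral angle mapper, ROI/margin/grid geometry, cell features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jamspec import (
    apply_margin,
    cell_feature,
    extract_features,
    pick_reference,
    roi_from_mask,
    sam_mask,
    spectral_angle,
    spectral_angle_image,
    subdivide,
)
from jamspec.calibrate import ReflectanceCube
from jamspec.segment import (
    DegenerateRoiError,
    EmptyRoiError,
    RegionOfInterest,
    UndefinedAngleError,
)


def _cube(R):
    return ReflectanceCube(R=np.asarray(R, dtype=float), wavelengths=None)


class TestSpectralAngle:
    def test_self_angle_zero(self):
        p = np.array([0.2, 0.5, 0.1])
        assert spectral_angle(p, p) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_is_half_pi(self):
        assert spectral_angle([1, 0], [0, 1]) == pytest.approx(np.pi / 2)

    def test_diagonal_is_quarter_pi(self):
        assert spectral_angle([1, 0], [1, 1]) == pytest.approx(np.pi / 4)

    @given(scale=st.floats(1e-6, 1e6), seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(8) + 0.01
        r = rng.random(8) + 0.01
        assert spectral_angle(scale * p, r) == pytest.approx(
            spectral_angle(p, r), abs=1e-7
        )

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        p, r = rng.random(10), rng.random(10)
        assert spectral_angle(p, r) == pytest.approx(spectral_angle(r, p))

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedAngleError):
            spectral_angle([0, 0], [1, 0])


class TestSamMask:
    def test_identical_pixels_all_true(self):
        r = np.array([0.3, 0.6, 0.2])
        cube = _cube(np.tile(r, (4, 5, 1)))
        assert sam_mask(cube, r).mask.all()

    def test_vectorized_equals_bruteforce_loop(self):
        """Vectorized SAM mask equals a per-pixel loop on 20 random cubes."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            R = rng.random((16, 16, 8)) + 1e-3
            r = rng.random(8) + 1e-3
            mask = sam_mask(_cube(R), r, threshold_rad=0.3).mask
            oracle = np.zeros((16, 16), dtype=bool)
            for i in range(16):
                for j in range(16):
                    oracle[i, j] = spectral_angle(R[i, j], r) <= 0.3
            assert np.array_equal(mask, oracle)

    def test_noiseless_scene_mask_matches_ground_truth(
        self, noiseless_capture, noiseless_cube
    ):
        ref = pick_reference(noiseless_cube)
        mask = sam_mask(noiseless_cube, ref)
        assert np.array_equal(mask.mask, noiseless_capture.jam_truth)

    def test_invalid_pixels_excluded(self):
        r = np.array([0.3, 0.6])
        R = np.tile(r, (3, 3, 1))
        invalid = np.zeros((3, 3), dtype=bool)
        invalid[1, 1] = True
        cube = ReflectanceCube(R=R, wavelengths=None, invalid=invalid)
        mask = sam_mask(cube, r).mask
        assert not mask[1, 1] and mask.sum() == 8

    def test_threshold_is_inclusive(self):
        r = np.array([1.0, 0.0])
        p = np.array([np.cos(0.2), np.sin(0.2)])  # exactly 0.2 rad away
        cube = _cube(p[None, None, :])
        assert sam_mask(cube, r, threshold_rad=0.2).mask[0, 0]


class TestPickReference:
    def test_constant_region_returns_that_spectrum(self):
        s = np.array([0.1, 0.4, 0.3])
        cube = _cube(np.tile(s, (10, 10, 1)))
        assert np.allclose(pick_reference(cube), s)

    def test_median_excludes_single_outlier(self):
        s = np.array([0.2, 0.2])
        R = np.tile(s, (10, 10, 1))
        R[5, 5] = [5.0, 5.0]  # inside the central patch
        assert np.allclose(pick_reference(_cube(R)), s)

    def test_reference_close_to_template_under_noise(self, tiny_design):
        """Central-patch median lands within 0.05 rad of the true template."""
        from jamspec import (
            calibrate_capture,
            default_spectral_model,
            enumerate_design,
            render_scene,
        )

        model = default_spectral_model(
            tiny_design.wavelengths, tiny_design.cultivars, noise_sd=0.01
        )
        meta = enumerate_design(tiny_design)[0]
        cube = calibrate_capture(render_scene(meta, model, tiny_design, 3))
        tpl = model.mean_spectrum(meta.cultivar, meta.sugar_pct)
        assert spectral_angle(pick_reference(cube), tpl) < 0.05


class TestRoiAndMargin:
    def test_single_pixel_box(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 5] = True
        roi = roi_from_mask(mask)
        assert (roi.row_min, roi.row_max, roi.col_min, roi.col_max) == (3, 4, 5, 6)

    def test_ten_percent_margin_arithmetic(self):
        roi = RegionOfInterest(0, 100, 0, 60)
        inner = apply_margin(roi, 0.10)
        assert (inner.row_min, inner.row_max) == (10, 90)
        assert (inner.col_min, inner.col_max) == (6, 54)
        assert inner.height == 80 and inner.width == 48

    def test_zero_margin_is_identity(self):
        roi = RegionOfInterest(2, 9, 4, 11)
        assert apply_margin(roi, 0.0) == roi

    def test_all_false_mask_raises(self):
        with pytest.raises(EmptyRoiError):
            roi_from_mask(np.zeros((5, 5), dtype=bool))

    def test_margin_fraction_validated(self):
        # a fraction of 0.5 or more would always collapse the box
        with pytest.raises(ValueError):
            apply_margin(RegionOfInterest(0, 10, 0, 10), 0.5)

    def test_empty_roi_rejected_at_construction(self):
        with pytest.raises(DegenerateRoiError):
            RegionOfInterest(5, 5, 0, 3)


class TestSubdivide:
    def test_exact_quarters_of_512(self):
        cells = subdivide(RegionOfInterest(0, 512, 0, 512), 4)
        assert len(cells) == 16
        assert all(c.height == 128 and c.width == 128 for c in cells)

    def test_g1_identity(self):
        roi = RegionOfInterest(3, 40, 7, 29)
        assert subdivide(roi, 1) == [roi]

    def test_remainder_goes_to_leading_cells(self):
        cells = subdivide(RegionOfInterest(0, 10, 0, 10), 3)
        rows = sorted({(c.row_min, c.row_max) for c in cells})
        assert rows == [(0, 4), (4, 7), (7, 10)]

    def test_partition_property_brute_force(self):
        """Cells tile the box exactly for all g in 1..5 and sizes 5..40."""
        for g in range(1, 6):
            for h in range(5, 41, 7):
                for w in range(5, 41, 7):
                    roi = RegionOfInterest(2, 2 + h, 3, 3 + w)
                    cells = subdivide(roi, g)
                    cover = np.zeros((h + 4, w + 6), dtype=int)
                    for c in cells:
                        cover[c.row_min : c.row_max, c.col_min : c.col_max] += 1
                    inside = cover[2 : 2 + h, 3 : 3 + w]
                    assert inside.min() == inside.max() == 1
                    assert cover.sum() == h * w
                    sizes_h = {c.height for c in cells}
                    sizes_w = {c.width for c in cells}
                    assert max(sizes_h) - min(sizes_h) <= 1
                    assert max(sizes_w) - min(sizes_w) <= 1

    def test_too_small_roi_raises(self):
        with pytest.raises(DegenerateRoiError):
            subdivide(RegionOfInterest(0, 2, 0, 10), 3)


class TestCellFeature:
    def test_identical_pixels_give_unit_template(self):
        s = np.array([3.0, 4.0])
        cube = _cube(np.tile(s, (6, 6, 1)))
        mask = np.ones((6, 6), dtype=bool)
        feat = cell_feature(cube, mask, RegionOfInterest(0, 6, 0, 6), 1, (0, 0))
        assert np.allclose(feat.feature, [0.6, 0.8])
        assert feat.n_pixels == 36

    def test_mask_excludes_background_from_mean(self):
        cube_data = np.tile([1.0, 0.0], (4, 4, 1))
        cube_data[0, 0] = [0.0, 9.0]
        mask = np.ones((4, 4), dtype=bool)
        mask[0, 0] = False
        feat = cell_feature(
            _cube(cube_data), mask, RegionOfInterest(0, 4, 0, 4), 1, (0, 0)
        )
        assert np.allclose(feat.feature, [1.0, 0.0])
        unmasked = cell_feature(
            _cube(cube_data),
            np.ones((4, 4), dtype=bool),
            RegionOfInterest(0, 4, 0, 4),
            1,
            (0, 0),
        )
        assert not np.allclose(unmasked.feature, feat.feature)

    def test_sparse_cell_dropped(self):
        cube = _cube(np.ones((4, 4, 3)))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        assert (
            cell_feature(cube, mask, RegionOfInterest(0, 4, 0, 4), 1, (0, 0),
                         min_pixels=5)
            is None
        )

    def test_unit_norm_invariant(self, noiseless_cube):
        for feat in extract_features(noiseless_cube, 3):
            assert np.linalg.norm(feat.feature) == pytest.approx(1.0, abs=1e-9)


def test_end_to_end_noiseless_features_equal_template(
    noiseless_capture, noiseless_cube, noiseless_model
):
    """Every surviving cell feature equals the unit-norm jam template."""
    meta = noiseless_capture.meta
    tpl = noiseless_model.mean_spectrum(meta.cultivar, meta.sugar_pct)
    tpl = tpl / np.linalg.norm(tpl)
    for g in range(1, 6):
        feats = extract_features(noiseless_cube, g)
        assert feats, f"no cells survived at g={g}"
        for feat in feats:
            assert np.abs(feat.feature - tpl).max() < 1e-10


def test_angle_image_matches_scalar_angle():
    rng = np.random.default_rng(4)
    R = rng.random((5, 5, 6)) + 0.01
    r = rng.random(6) + 0.01
    img = spectral_angle_image(R, r)
    for i in range(5):
        for j in range(5):
            assert img[i, j] == pytest.approx(spectral_angle(R[i, j], r), abs=1e-10)
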