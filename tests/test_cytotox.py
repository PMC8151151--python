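"""Fragmentation scoring, specific lysis and recruitment-cytotoxicity coupling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from skimage.draw import disk as draw_disk

import spherotox as st

from conftest import disk_mask


HIGHRES = st.FragmentationParams(pixel_size=1.0, nucleus_diameter_um=20.0)


def _blob_image(shape, intact_centers, intact_r, frag_centers, frag_r,
                intact_v=0.8, frag_v=1.0):
    img = np.zeros(shape)
    n_i = n_f = 0
    for c in intact_centers:
        rr, cc = draw_disk(c, intact_r, shape=shape)
        img[rr, cc] = intact_v
        n_i += len(rr)
    for c in frag_centers:
        rr, cc = draw_disk(c, frag_r, shape=shape)
        img[rr, cc] = frag_v
        n_f += len(rr)
    return img, n_i, n_f


class TestHighres:
    def test_only_intact_blobs_scores_zero(self):
        img, _, _ = _blob_image((200, 200), [(50, 50), (120, 60), (60, 140)], 10, [], 2)
        assert st.fragmentation_highres(img, np.ones((200, 200), bool), HIGHRES) == 0.0

    def test_only_small_blobs_scores_one(self):
        img, _, _ = _blob_image((200, 200), [], 10,
                                [(40, 40), (90, 60), (150, 150), (60, 170),
                                 (120, 120), (170, 40), (30, 130)], 3)
        assert st.fragmentation_highres(img, np.ones((200, 200), bool), HIGHRES) == 1.0

    def test_pixel_count_oracle(self):
        img, n_i, n_f = _blob_image(
            (220, 220),
            [(50, 50), (130, 60), (60, 150)], 11,
            [(180, 180), (190, 130), (120, 190), (200, 60)], 3,
        )
        expect = n_f / (n_i + n_f)
        got = st.fragmentation_highres(img, np.ones((220, 220), bool), HIGHRES)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_empty_mask_and_dark_frame_are_missing(self):
        assert np.isnan(
            st.fragmentation_highres(np.zeros((50, 50)), np.zeros((50, 50), bool), HIGHRES)
        )
        assert np.isnan(
            st.fragmentation_highres(np.zeros((50, 50)), np.ones((50, 50), bool), HIGHRES)
        )

    def test_multiplicative_rescaling_invariance(self):
        img, _, _ = _blob_image(
            (220, 220), [(50, 50), (130, 60)], 11, [(180, 180), (200, 60)], 3
        )
        mask = np.ones((220, 220), bool)
        f1 = st.fragmentation_highres(img, mask, HIGHRES)
        f2 = st.fragmentation_highres(0.37 * img, mask, HIGHRES)
        assert f1 == pytest.approx(f2, abs=1e-12)


class TestLowres:
    def test_smooth_signal_scores_below_false_positive_floor(self):
        yy, xx = np.mgrid[0:120, 0:120]
        img = 0.5 * np.exp(-((yy - 60) ** 2 + (xx - 60) ** 2) / (2 * 40.0**2))
        mask = disk_mask((120, 120), (60, 60), 50)
        f = st.fragmentation_lowres(img, mask, st.FragmentationParams(pixel_size=4.0))
        assert f <= 0.05

    def test_multiplicative_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.random((100, 100))
        mask = disk_mask((100, 100), (50, 50), 40)
        params = st.FragmentationParams(pixel_size=4.0)
        f1 = st.fragmentation_lowres(img, mask, params)
        f2 = st.fragmentation_lowres(5.0 * img, mask, params)
        assert f1 == pytest.approx(f2, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((60, 60))
        mask = disk_mask((60, 60), (30, 30), 20)
        f = st.fragmentation_lowres(img, mask, st.FragmentationParams(pixel_size=4.0))
        assert 0.0 <= f <= 1.0

    def test_empty_mask_is_missing(self):
        f = st.fragmentation_lowres(np.zeros((40, 40)), np.zeros((40, 40), bool))
        assert np.isnan(f)

    def test_scores_track_true_fragment_load(self):
        res = st.validation.lowres_scorer_sweep(seed=1, n_levels=5)
        s = res["scored_fractions"]
        assert s[-1] > s[0] + 0.02


def _series(times, vals, sid=1):
    return st.FragmentationSeries(sid, np.asarray(times, float),
                                  np.asarray(vals, float))


class TestSpecificLysis:
    def test_no_treatment_effect_is_zero(self):
        t = np.arange(5.0)
        ls = st.specific_lysis(_series(t, [0.2] * 5), _series(t, [0.2] * 5))
        assert np.allclose(ls.specific_lysis, 0.0)

    def test_full_fragmentation_is_full_lysis(self):
        t = np.arange(5.0)
        ls = st.specific_lysis(_series(t, [1.0] * 5), _series(t, [0.2] * 5))
        assert np.allclose(ls.specific_lysis, 100.0)

    def test_direct_arithmetic_oracle(self):
        t = np.arange(4.0)
        ls = st.specific_lysis(_series(t, [0.4] * 4), _series(t, [0.1] * 4))
        assert np.allclose(ls.specific_lysis, 100.0 * 0.3 / 0.9)

    def test_negative_protection_clamped_to_zero(self):
        t = np.arange(4.0)
        ls = st.specific_lysis(_series(t, [0.1] * 4), _series(t, [0.3] * 4))
        assert np.allclose(ls.specific_lysis, 0.0)

    def test_saturated_control_is_missing(self):
        t = np.arange(4.0)
        ls = st.specific_lysis(_series(t, [0.5] * 4), _series(t, [1.0] * 4))
        assert np.isnan(ls.specific_lysis).all()

    def test_control_resampled_onto_treated_grid(self):
        ls = st.specific_lysis(
            _series([0.0, 1.0, 2.0, 3.0], [0.4] * 4),
            _series([0.0, 3.0], [0.0, 0.3]),  # linear control: 0.1 at t=1
        )
        assert ls.specific_lysis[0] == pytest.approx(100 * 0.4)
        assert ls.specific_lysis[1] == pytest.approx(100.0 * 0.3 / 0.9, rel=1e-9)
        assert ls.specific_lysis[3] == pytest.approx(100.0 * 0.1 / 0.7, rel=1e-9)

    def test_disjoint_time_ranges_rejected(self):
        with pytest.raises(ValueError):
            st.specific_lysis(
                _series([0.0, 1.0, 2.0], [0.1] * 3), _series([5.0, 6.0], [0.1] * 2)
            )


class TestCoupling:
    def test_identical_shapes_have_zero_lag(self):
        t = np.arange(0.0, 40.0, 1.0)
        y = st.sigmoid_model(t, 0.0, 0.5, 0.3, 15.0)
        curve = st.RecruitmentCurve(1, t, y)
        frag = _series(t, np.clip(y, 0, 1))
        pairs, lag = st.coupling_curve(curve, frag)
        assert lag == pytest.approx(0.0, abs=1e-9)
        assert pairs.shape[1] == 3

    def test_time_shift_recovered_as_lag(self):
        t = np.arange(0.0, 60.0, 1.0)
        y = st.sigmoid_model(t, 0.0, 0.5, 0.4, 15.0)
        y_shift = st.sigmoid_model(t, 0.0, 0.5, 0.4, 27.0)
        _, lag = st.coupling_curve(st.RecruitmentCurve(1, t, y), _series(t, y_shift))
        assert lag == pytest.approx(12.0, abs=0.05)

    def test_flat_fragmentation_has_undefined_lag(self):
        t = np.arange(0.0, 40.0, 1.0)
        y = st.sigmoid_model(t, 0.0, 0.5, 0.3, 15.0)
        _, lag = st.coupling_curve(st.RecruitmentCurve(1, t, y), _series(t, np.zeros_like(t)))
        assert np.isnan(lag)

    def test_nonoverlapping_series_rejected(self):
        t1 = np.arange(0.0, 10.0)
        t2 = np.arange(20.0, 30.0)
        with pytest.raises(ValueError):
            st.coupling_curve(
                st.RecruitmentCurve(1, t1, np.linspace(0, 1, 10)),
                _series(t2, np.linspace(0, 1, 10)),
            )

    def test_half_crossing_is_baseline_corrected(self):
        t = np.arange(0.0, 10.0)
        v = np.array([0.4, 0.4, 0.4, 0.4, 0.5, 0.6, 0.7, 0.8, 0.8, 0.8])
        # rise from 0.4 to 0.8: half-rise level 0.6 is crossed at t=5
        assert st.half_crossing_time(t, v) == pytest.approx(5.0)


class TestSeriesValidation:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            _series([0.0, 1.0], [0.5, 1.5])

    def test_lysis_bounds_enforced(self):
        with pytest.raises(ValueError):
            st.LysisSeries(np.array([0.0]), np.array([120.0]))
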