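"""Recruitment measurement, sigmoid fitting and cohort analyses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import spherotox as st
from spherotox.segmentation import TrackEntry

from conftest import disk_mask


def _stack_from_frames(frames, pixel_size=4.0):
    pixels = np.asarray(frames, dtype=float)[:, None]
    return st.CalibratedStack(
        pixels=np.clip(pixels, 0, 1),
        channel_roles=("EFF",),
        times=np.arange(pixels.shape[0], dtype=float),
        pixel_size=pixel_size,
    )


def _one_track(mask, n_frames):
    from skimage.measure import regionprops

    p = regionprops(mask.astype(int))[0]
    entries = [
        TrackEntry(frame=f, mask=mask, centroid=tuple(map(float, p.centroid)),
                   area_px=float(p.area))
        for f in range(n_frames)
    ]
    return st.SpheroidTrack(id=1, pixel_size=4.0, entries=entries)


class TestMeasureRecruitment:
    def test_uniform_frame_measures_zero(self):
        frames = np.full((3, 60, 60), 0.4)
        mask = disk_mask((60, 60), (30, 30), 12)
        curves = st.measure_recruitment(
            _stack_from_frames(frames), [_one_track(mask, 3)], "EFF"
        )
        assert np.allclose(curves[0].values, 0.0, atol=1e-12)

    def test_additive_offset_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.random((2, 60, 60)) * 0.4
        mask = disk_mask((60, 60), (30, 30), 12)
        track = [_one_track(mask, 2)]
        v0 = st.measure_recruitment(_stack_from_frames(base), track, "EFF")[0].values
        v1 = st.measure_recruitment(_stack_from_frames(base + 0.3), track, "EFF")[0].values
        assert np.allclose(v0, v1, atol=1e-12)

    def test_multiplicative_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.random((2, 60, 60)) * 0.3
        mask = disk_mask((60, 60), (30, 30), 12)
        track = [_one_track(mask, 2)]
        v0 = st.measure_recruitment(_stack_from_frames(base), track, "EFF")[0].values
        v2 = st.measure_recruitment(_stack_from_frames(2 * base), track, "EFF")[0].values
        assert np.allclose(v2, 2 * v0, atol=1e-12)

    def test_pixel_sum_oracle(self):
        # inside mean 0.30, outside 0.10 everywhere -> value 0.20
        mask = disk_mask((80, 80), (40, 40), 15)
        frame = np.where(mask, 0.30, 0.10)
        curves = st.measure_recruitment(
            _stack_from_frames(frame[None]), [_one_track(mask, 1)], "EFF"
        )
        # brute-force oracle
        guard = 5  # 20 um / 4 um
        from scipy.ndimage import binary_dilation

        outside = ~binary_dilation(mask, np.ones((2 * guard + 1,) * 2, bool))
        expect = frame[mask].mean() - np.median(frame[outside])
        assert curves[0].values[0] == pytest.approx(expect, abs=1e-12)
        assert curves[0].values[0] == pytest.approx(0.20, abs=1e-12)

    def test_missing_mask_recorded_as_nan(self):
        mask = disk_mask((60, 60), (30, 30), 12)
        track = _one_track(mask, 1)  # only frame 0
        frames = np.full((3, 60, 60), 0.2)
        curves = st.measure_recruitment(_stack_from_frames(frames), [track], "EFF")
        assert np.isfinite(curves[0].values[0])
        assert np.isnan(curves[0].values[1:]).all()

    def test_empty_track_list_rejected(self, small_scene):
        _, _, stack = small_scene
        with pytest.raises(ValueError):
            st.measure_recruitment(stack, [], "EFF")


class TestFitSigmoid:
    def test_noiseless_recovery_in_reported_parameter_regime(self):
        t = np.arange(0.0, 48.0, 1.0)
        a, b, k, tau = 0.0, 0.06, 0.29, 5.9
        f = st.fit_sigmoid(st.RecruitmentCurve(1, t, st.sigmoid_model(t, a, b, k, tau)))
        assert f.b == pytest.approx(b, rel=1e-4)
        assert f.k == pytest.approx(k, rel=1e-4)
        assert f.tau == pytest.approx(tau, rel=1e-4)
        assert abs(f.a - a) <= 1e-4 * b
        assert f.identifiable and f.converged

    @pytest.mark.parametrize("k", [0.05, 0.2, 1.0])
    @pytest.mark.parametrize("tau", [8.0, 30.0])
    def test_noiseless_recovery_across_rate_grid(self, k, tau):
        t = np.arange(0.0, 48.0, 1.0)
        y = st.sigmoid_model(t, 0.1, 0.5, k, tau)
        f = st.fit_sigmoid(st.RecruitmentCurve(1, t, y))
        assert f.k == pytest.approx(k, rel=1e-4)
        assert f.tau == pytest.approx(tau, rel=1e-4)

    def test_midpoint_identity_holds_exactly(self):
        t = np.arange(0.0, 40.0, 2.0)
        rng = np.random.default_rng(2)
        y = st.sigmoid_model(t, 0.05, 0.3, 0.25, 12.0) + rng.normal(0, 0.01, t.shape)
        f = st.fit_sigmoid(st.RecruitmentCurve(1, t, y))
        assert f.predict(np.array([f.tau]))[0] == pytest.approx(f.a + f.b / 2, abs=1e-12)

    def test_flat_curve_degenerates_gracefully(self):
        t = np.arange(0.0, 10.0, 1.0)
        f = st.fit_sigmoid(st.RecruitmentCurve(1, t, np.full_like(t, 0.2)))
        assert not f.identifiable
        assert f.b == 0.0
        assert f.a == pytest.approx(0.2)
        assert np.isnan(f.k) and np.isnan(f.tau)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            st.fit_sigmoid(st.RecruitmentCurve(1, np.arange(3.0), np.arange(3.0)))

    def test_nan_values_dropped_before_fitting(self):
        t = np.arange(0.0, 30.0, 1.0)
        y = st.sigmoid_model(t, 0.0, 0.4, 0.3, 10.0)
        y[::7] = np.nan
        f = st.fit_sigmoid(st.RecruitmentCurve(1, t, y))
        assert f.tau == pytest.approx(10.0, rel=1e-3)

    def test_noisy_recovery_monte_carlo(self):
        # 15-min cadence, transition mid-window: an informative design in
        # which 10% amplitude noise still allows <10% error on tau and k
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 48.0, 0.25)
        clean = st.sigmoid_model(t, 0.0, 0.06, 0.29, 15.0)
        errs_tau, errs_k = [], []
        for _ in range(20):
            y = clean + rng.normal(0, 0.006, t.shape)
            f = st.fit_sigmoid(st.RecruitmentCurve(1, t, y))
            errs_tau.append(abs(f.tau - 15.0) / 15.0)
            errs_k.append(abs(f.k - 0.29) / 0.29)
        assert np.median(errs_tau) < 0.10
        assert np.median(errs_k) < 0.10


def _fit(tau=5.0, k=0.3, b=0.1, a=0.0, identifiable=True):
    return st.SigmoidFit(
        spheroid_id=0, a=a, b=b, k=k, tau=tau, rss=0.0,
        converged=True, identifiable=identifiable,
    )


class TestSummarize:
    def test_identical_fits_have_zero_sd(self):
        out = st.summarize_recruitment([_fit()] * 3)
        assert out["all"]["tau"] == (5.0, 0.0)
        assert out["all"]["n"] == 3

    def test_hand_computed_mean_and_sd(self):
        fits = [_fit(tau=x) for x in (4.0, 6.0, 8.0)]
        mean, sd = st.summarize_recruitment(fits)["all"]["tau"]
        assert mean == pytest.approx(6.0)
        assert sd == pytest.approx(2.0)

    def test_non_identifiable_fits_excluded_and_counted(self):
        fits = [_fit() for _ in range(4)] + [_fit(identifiable=False)]
        out = st.summarize_recruitment(fits)
        assert out["all"]["n"] == 4
        assert out["all"]["n_excluded"] == 1

    def test_small_group_omitted_with_warning(self):
        fits = [_fit(), _fit(identifiable=False)]
        with pytest.warns(UserWarning, match="omitted"):
            out = st.summarize_recruitment(fits, ["g1", "g1"])
        assert out == {}


class TestDensityResponse:
    def test_exact_linearity(self):
        c = 2e-6
        fbd = {
            d: [_fit(b=c * d, tau=5.0 + i) for i in range(3)]
            for d in (1e5, 2e5, 5e5)
        }
        res = st.density_response(fbd)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(c)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_tau_samples_have_zero_ks(self):
        fbd = {
            d: [_fit(tau=t) for t in (3.0, 5.0, 7.0)] for d in (1e5, 2e5, 5e5)
        }
        assert st.density_response(fbd)["max_ks_tau"] == 0.0

    def test_too_few_densities_rejected(self):
        with pytest.raises(ValueError):
            st.density_response({1e5: [_fit()] * 3, 2e5: [_fit()] * 3})


class TestClusteringScale:
    def test_csr_pattern_shows_no_clustering(self):
        rng = np.random.default_rng(0)
        pts = rng.random((200, 2)) * 1000
        length, _ = st.clustering_scale(pts, (1000, 1000), n_null=99, rng_seed=1)
        assert length <= 5.0

    def test_small_gaussian_clusters_detected_at_their_scale(self):
        rng = np.random.default_rng(3)
        centers = np.stack(
            np.meshgrid(np.arange(100, 1000, 200), np.arange(100, 1000, 200))
        ).reshape(2, -1).T
        pts = np.concatenate([c + rng.normal(0, 5, (8, 2)) for c in centers])
        length, _ = st.clustering_scale(pts, (1000, 1000), n_null=99, rng_seed=1)
        assert 10.0 <= length <= 30.0

    def test_coincident_points_excess_in_first_bin_only(self):
        pts = np.full((40, 2), 500.0)
        length, info = st.clustering_scale(pts, (1000, 1000), n_null=49, rng_seed=1)
        assert length == 5.0
        assert info["exceed"][0] and not info["exceed"][1:].any()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            st.clustering_scale(np.zeros((10, 2)), (100, 100))


@settings(max_examples=20, deadline=None)
@given(hst.integers(min_value=0, max_value=2**31 - 1))
def test_recruitment_curve_requires_increasing_times(seed):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.random(6)) * 10
    if len(np.unique(t)) < 6:
        t = np.arange(6.0)
    st.RecruitmentCurve(1, t, rng.random(6))  # valid
    with pytest.raises(ValueError):
        st.RecruitmentCurve(1, t[::-1], rng.random(6))
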