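import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumispark.background import (
    BackgroundEstimate,
    RoiPair,
    compute_eb,
    compute_gb,
    default_roi_pair,
    frame_thresholds,
    select_reference_frames,
)
from lumispark.phantom import CameraModel, make_embryo_phantom, render_luminescence_movie


def _pair(shape=(16, 16)):
    roi1 = np.zeros(shape, bool)
    roi2 = np.zeros(shape, bool)
    roi1[8:12, 4:12] = True
    roi2[2:6, 4:12] = True
    return RoiPair(roi1, roi2)


def _movie_with_means(roi1_means, roi2_means, pair):
    frames = np.zeros((len(roi1_means), *pair.roi1.shape))
    for i, (a, b) in enumerate(zip(roi1_means, roi2_means)):
        frames[i][pair.roi1] = a
        frames[i][pair.roi2] = b
    return frames


class TestGB:
    def test_constant_region_gives_the_constant(self):
        frame = np.full((16, 16), 7.0)
        assert compute_gb(frame, _pair().roi2) == 7.0

    def test_hand_computed_example(self):
        """Pixels {10, 12, 14}: mean 12, sample SD 2 → GB = 16."""
        frame = np.zeros((4, 4))
        roi2 = np.zeros((4, 4), bool)
        roi2[0, :3] = True
        frame[0, :3] = [10, 12, 14]
        assert compute_gb(frame, roi2) == pytest.approx(16.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            compute_gb(np.zeros((4, 4)), np.zeros((4, 4), bool))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(-50, 50))
    def test_translation_equivariance(self, k):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 10, (16, 16))
        roi2 = _pair().roi2
        assert compute_gb(frame + k, roi2) == pytest.approx(
            compute_gb(frame, roi2) + k, abs=1e-9)

    def test_monotone_in_roi2_spread(self):
        """Increasing ROI2 noise SD never lowers GB."""
        pair = _pair()
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (16, 16))
        gbs = [compute_gb(10 + s * base, pair.roi2) for s in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(gbs) >= 0)


class TestEB:
    def test_constant_differences(self):
        """All 15 per-frame differences equal 5 → EB = 5."""
        pair = _pair()
        frames = _movie_with_means([8.0] * 15, [3.0] * 15, pair)
        assert compute_eb(frames, pair, range(15)) == pytest.approx(5.0)

    def test_hand_computed_spread(self):
        """Differences {4, 6} repeated: EB = mean + 2 × sample SD."""
        pair = _pair()
        diffs = [4.0, 6.0] * 7 + [5.0]
        frames = _movie_with_means([d + 1 for d in diffs], [1.0] * 15, pair)
        expected = np.mean(diffs) + 2 * np.std(diffs, ddof=1)
        assert compute_eb(frames, pair, range(15)) == pytest.approx(expected)

    def test_identical_rois_give_zero(self):
        pair = _pair()
        frames = _movie_with_means([2.0] * 15, [2.0] * 15, pair)
        assert compute_eb(frames, pair, range(15)) == 0.0

    def test_negative_eb_clamped(self):
        pair = _pair()
        frames = _movie_with_means([1.0] * 15, [5.0] * 15, pair)
        assert compute_eb(frames, pair, range(15)) == 0.0

    def test_too_few_reference_frames_rejected(self):
        pair = _pair()
        frames = _movie_with_means([1.0] * 15, [1.0] * 15, pair)
        with pytest.raises(ValueError):
            compute_eb(frames, pair, range(10))


class TestThresholds:
    def test_noise_movie_suprathreshold_fraction_is_small(self):
        """Mean + 2 SD rule leaves only a few percent of pixels above
        threshold in an event-free unimodal-noise movie."""
        rng = np.random.default_rng(2)
        frames = np.clip(rng.normal(100, 5, (60, 32, 32)), 0, None)
        pair = _pair((32, 32))
        est = frame_thresholds(frames, pair)
        frac = np.mean([(f > t).mean()
                        for f, t in zip(frames, est.threshold_per_frame)])
        assert 0.0 < frac < 0.05

    def test_constant_movie_has_no_suprathreshold_pixel(self):
        pair = _pair()
        frames = np.full((20, 16, 16), 4.0)
        est = frame_thresholds(frames, pair)
        assert np.all(est.threshold_per_frame == 4.0)
        assert not np.any(frames > est.threshold_per_frame[:, None, None])

    def test_brightening_roi1_raises_threshold_by_same_amount(self):
        pair = _pair()
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 2, (30, 16, 16))
        b = 5.0
        brighter = frames.copy()
        brighter[:, pair.roi1] += b
        ref = list(range(15))
        t0 = frame_thresholds(frames, pair, ref).threshold_per_frame
        t1 = frame_thresholds(brighter, pair, ref).threshold_per_frame
        assert np.allclose(t1 - t0, b)

    def test_whole_movie_shift_moves_every_threshold(self):
        pair = _pair()
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 2, (30, 16, 16))
        ref = list(range(15))
        t0 = frame_thresholds(frames, pair, ref).threshold_per_frame
        t1 = frame_thresholds(frames + 3.0, pair, ref).threshold_per_frame
        assert np.allclose(t1 - t0, 3.0)

    def test_auto_selection_picks_dimmest_frames(self):
        roi1 = _pair().roi1
        frames = np.zeros((20, 16, 16))
        bright = [3, 7, 11]
        for i in bright:
            frames[i][roi1] = 100.0
        chosen = select_reference_frames(frames, roi1, n=15)
        assert not set(bright) & set(chosen.tolist())

    def test_eb_recovers_substrate_glow_on_simulator_output(self):
        """On an event-free rendered movie, EB sits near the glow's mean
        per-frame contribution (ROI1 − ROI2)."""
        ph = make_embryo_phantom()
        glow = 2.0
        cam = CameraModel.for_binned_shape(ph.image_shape,
                                           integration_time=0.213,
                                           substrate_glow_rate=glow)
        rates = np.zeros((ph.n_somites, 150))
        mv = render_luminescence_movie(ph, rates, cam, seed=9)
        pair = default_roi_pair(ph)
        ref = list(range(15))
        est = frame_thresholds(mv.frames, pair, ref)
        diffs = np.array([mv.frames[i][pair.roi1].mean()
                          - mv.frames[i][pair.roi2].mean() for i in ref])
        expected = glow * cam.integration_time
        assert est.eb > 0
        assert abs(est.eb - expected) <= 3 * np.std(diffs, ddof=1)

    def test_estimate_invariant_threshold_not_below_gb(self):
        with pytest.raises(ValueError):
            BackgroundEstimate(np.array([2.0]), -1.0, np.array([0.5]),
                               np.array([0]))


class TestRoiPair:
    def test_mismatched_counts_rejected(self):
        roi1 = np.zeros((8, 8), bool)
        roi2 = np.zeros((8, 8), bool)
        roi1[0, :4] = True
        roi2[4, :3] = True
        with pytest.raises(ValueError):
            RoiPair(roi1, roi2)

    def test_overlap_rejected(self):
        roi = np.zeros((8, 8), bool)
        roi[0, :4] = True
        with pytest.raises(ValueError):
            RoiPair(roi, roi)

    def test_default_pair_off_embryo(self, phantom):
        pair = default_roi_pair(phantom)
        assert pair.roi1.sum() == pair.roi2.sum()
        assert not np.any(pair.roi2 & phantom.trunk_mask)
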