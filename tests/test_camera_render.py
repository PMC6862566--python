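import numpy as np
import pytest

from lumispark.phantom import (
    BleachingModel,
    CameraModel,
    SpikeSchedule,
    TransientWaveform,
    TwitchModel,
    acquisition_frequency,
    field_of_view,
    render_fret_movie,
    render_luminescence_movie,
    render_transmitted_movie,
    somite_ca_traces,
    PropagationParams,
)


class TestCalibration:
    def test_published_luminescence_field_of_view(self):
        assert field_of_view(512, 4, 12.8) == pytest.approx(1638.4)

    def test_published_split_field_of_view(self):
        assert field_of_view(2048, 4, 2.9, split_halves=2) == pytest.approx(742.4)

    def test_integration_to_frequency(self):
        assert acquisition_frequency(0.084) == 11.9
        assert acquisition_frequency(0.213) == 4.7
        assert acquisition_frequency(1.0) == 1.0

    def test_zero_inputs_rejected(self):
        with pytest.raises(ValueError):
            field_of_view(512, 0, 12.8)
        with pytest.raises(ValueError):
            acquisition_frequency(0.0)

    def test_binning_must_divide_sensor(self):
        with pytest.raises(ValueError):
            CameraModel(sensor_pixels=(510, 512), binning=4)


class TestLuminescenceRender:
    def test_zero_rates_and_zero_noise_give_zero_movie(self, small_phantom):
        cam = CameraModel.for_binned_shape(small_phantom.image_shape,
                                           read_noise_sd=0.0,
                                           substrate_glow_rate=0.0,
                                           dark_rate=0.0)
        rates = np.zeros((small_phantom.n_somites, 20))
        mv = render_luminescence_movie(small_phantom, rates, cam, seed=0)
        assert np.all(mv.frames == 0)

    def test_poisson_mean_matches_analytic_rate(self, small_phantom):
        """Monte-Carlo per-pixel mean ≈ gain × rate × Δt within 3 SE."""
        r = 7.0
        cam = CameraModel.for_binned_shape(small_phantom.image_shape,
                                           integration_time=0.2, gain=2.0,
                                           read_noise_sd=0.0,
                                           substrate_glow_rate=0.0,
                                           dark_rate=0.0)
        rates = np.full((small_phantom.n_somites, 400), r)
        mv = render_luminescence_movie(small_phantom, rates, cam, seed=1)
        px = mv.frames[:, small_phantom.trunk_mask]
        expected = cam.gain * r * cam.integration_time
        se = cam.gain * np.sqrt(r * cam.integration_time) / np.sqrt(px.size)
        assert abs(px.mean() - expected) < 3 * se

    def test_same_seed_bit_identical(self, small_phantom):
        cam = CameraModel.for_binned_shape(small_phantom.image_shape)
        rates = np.full((small_phantom.n_somites, 10), 3.0)
        a = render_luminescence_movie(small_phantom, rates, cam, seed=5)
        b = render_luminescence_movie(small_phantom, rates, cam, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_shape_mismatch_rejected(self, small_phantom):
        cam = CameraModel.for_binned_shape((32, 32))
        with pytest.raises(ValueError):
            render_luminescence_movie(small_phantom,
                                      np.zeros((small_phantom.n_somites, 5)),
                                      cam)


class TestFretRender:
    def _traces(self, ph, n=40, amp=1.0):
        sched = (SpikeSchedule([0.5], [amp], duration=n / 20.0) if amp
                 else SpikeSchedule(np.empty(0), np.empty(0), duration=n / 20.0))
        _, ca, _ = somite_ca_traces(ph, sched, TransientWaveform.cytosolic(),
                                    PropagationParams(), sampling=20.0)
        return ca

    def test_resting_noiseless_ratio_is_ratio_min(self, small_phantom):
        tw = TwitchModel()
        h, w = small_phantom.image_shape
        cam = CameraModel.for_binned_shape((h, 2 * w), integration_time=0.05)
        ca = np.zeros((small_phantom.n_somites, 30))
        mv = render_fret_movie(small_phantom, ca, tw, None, cam,
                               stochastic=False)
        donor = mv.frames[:, :, :w]
        fret = mv.frames[:, :, w:]
        ratio = fret[:, small_phantom.trunk_mask] / donor[:, small_phantom.trunk_mask]
        assert np.allclose(ratio, tw.ratio_min)

    def test_common_motion_cancels_in_ratio(self, small_phantom):
        """The motion factor multiplies both channels, so the pixel ratio is
        identical with and without it."""
        tw = TwitchModel()
        h, w = small_phantom.image_shape
        cam = CameraModel.for_binned_shape((h, 2 * w), integration_time=0.05)
        ca = self._traces(small_phantom)
        def ratio(motion):
            mv = render_fret_movie(small_phantom, ca, tw, None, cam,
                                   motion_amplitude=motion, stochastic=False)
            return mv.frames[:, :, w:] / np.maximum(mv.frames[:, :, :w], 1e-12)
        assert np.allclose(ratio(0.0), ratio(0.3), rtol=1e-5)  # float32 frames

    def test_same_seed_bit_identical(self, small_phantom):
        tw = TwitchModel()
        h, w = small_phantom.image_shape
        cam = CameraModel.for_binned_shape((h, 2 * w), integration_time=0.05)
        ca = self._traces(small_phantom, n=10)
        a = render_fret_movie(small_phantom, ca, tw, BleachingModel(), cam, seed=3)
        b = render_fret_movie(small_phantom, ca, tw, BleachingModel(), cam, seed=3)
        assert np.array_equal(a.frames, b.frames)


class TestTransmittedRender:
    def test_zero_displacement_is_static(self, small_phantom):
        sched = SpikeSchedule([1.0], [1.0], duration=5.0)
        cam = CameraModel.for_binned_shape(small_phantom.image_shape,
                                           integration_time=0.25)
        mv = render_transmitted_movie(small_phantom, sched, cam,
                                      displacement=0.0, stochastic=False)
        assert np.allclose(mv.frames, mv.frames[0])

    def test_single_event_gives_single_deviation_interval(self, small_phantom):
        from lumispark.contractions import edge_roi_pair

        sched = SpikeSchedule([2.0], [1.0], duration=6.0)
        cam = CameraModel.for_binned_shape(small_phantom.image_shape,
                                           integration_time=0.25)
        mv = render_transmitted_movie(small_phantom, sched, cam,
                                      stochastic=False)
        on, _ = edge_roi_pair(small_phantom)
        trace = mv.frames[:, on].mean(axis=1)
        deviating = ~np.isclose(trace, trace[0])
        # exactly one contiguous run of deviating frames
        runs = np.diff(deviating.astype(int))
        assert deviating.any()
        assert (runs == 1).sum() == 1 and (runs == -1).sum() == 1

    def test_roi_outside_embryo_unaffected(self, small_phantom):
        sched = SpikeSchedule([1.0], [1.0], duration=4.0)
        cam = CameraModel.for_binned_shape(small_phantom.image_shape,
                                           integration_time=0.25)
        mv = render_transmitted_movie(small_phantom, sched, cam,
                                      stochastic=False)
        from lumispark.contractions import edge_roi_pair
        _, off = edge_roi_pair(small_phantom)
        trace = mv.frames[:, off].mean(axis=1)
        assert np.allclose(trace, trace[0])

    def test_same_seed_bit_identical(self, small_phantom):
        sched = SpikeSchedule([1.0], [1.0], duration=3.0)
        cam = CameraModel.for_binned_shape(small_phantom.image_shape,
                                           integration_time=0.25)
        a = render_transmitted_movie(small_phantom, sched, cam, seed=2)
        b = render_transmitted_movie(small_phantom, sched, cam, seed=2)
        assert np.array_equal(a.frames, b.frames)
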