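import numpy as np
import pytest

from lumispark import fret
from lumispark.phantom import (
    BleachingModel,
    CameraModel,
    Movie,
    PropagationParams,
    SpikeSchedule,
    TransientWaveform,
    TwitchModel,
    render_fret_movie,
    somite_ca_traces,
    twitch_ratio_response,
)


def _fret_movie(ph, schedule, offset=(0, 0), stochastic=False, seed=0,
                rate=33.0, bleach=None):
    _, ca, _ = somite_ca_traces(ph, schedule, TransientWaveform.cytosolic(),
                                PropagationParams(), sampling=rate,
                                duration=schedule.duration)
    h, w = ph.image_shape
    cam = CameraModel.for_binned_shape((h, 2 * w), integration_time=1 / rate)
    return render_fret_movie(ph, ca, TwitchModel(), bleach, cam, seed=seed,
                             channel_offset=offset, stochastic=stochastic)


class TestSplitAndRegister:
    def test_aligned_halves_give_zero_offset(self, small_phantom):
        sched = SpikeSchedule([1.0], [1.0], duration=4.0)
        mv = _fret_movie(small_phantom, sched)
        _, _, offset = fret.split_and_register(mv, search_radius=4)
        assert offset == (0, 0)

    def test_synthetic_shift_recovered(self, small_phantom):
        sched = SpikeSchedule([1.0], [1.0], duration=4.0)
        mv = _fret_movie(small_phantom, sched, offset=(3, -2))
        _, _, offset = fret.split_and_register(mv, search_radius=5)
        assert offset == (3, -2)

    def test_registration_is_idempotent(self, small_phantom):
        sched = SpikeSchedule([1.0], [1.0], duration=4.0)
        mv = _fret_movie(small_phantom, sched, offset=(2, 1))
        donor, fret_stack, _ = fret.split_and_register(mv, search_radius=4)
        realigned = np.concatenate([donor, fret_stack], axis=2)
        mv2 = Movie(realigned, mv.frame_interval, mv.pixel_scale)
        _, _, offset2 = fret.split_and_register(mv2, search_radius=4)
        assert offset2 == (0, 0)

    def test_edge_peak_warns(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 1, (1, 16, 32))
        mv = Movie(frames, 0.03, 2.9)
        with pytest.warns(UserWarning, match="misregistration"):
            fret.split_and_register(mv, search_radius=1)

    def test_odd_width_rejected(self):
        mv = Movie(np.ones((2, 8, 9)), 0.03, 2.9)
        with pytest.raises(ValueError):
            fret.split_and_register(mv)


class TestRatioStack:
    def test_constant_factor_ratio(self):
        donor = np.full((3, 8, 8), 10.0)
        rm = fret.ratio_stack(donor, 2.0 * donor)
        assert np.allclose(rm.ratio_stack[rm.validity_mask], 2.0)

    def test_common_multiplicative_perturbation_cancels(self):
        rng = np.random.default_rng(1)
        donor = rng.uniform(5, 10, (6, 8, 8))
        acc = rng.uniform(5, 10, (6, 8, 8))
        motion = rng.uniform(0.5, 1.5, 6)[:, None, None]
        a = fret.ratio_stack(donor, acc)
        b = fret.ratio_stack(donor * motion, acc * motion)
        assert np.allclose(a.ratio_stack[a.validity_mask & b.validity_mask],
                           b.ratio_stack[a.validity_mask & b.validity_mask])

    def test_empty_validity_rejected(self):
        with pytest.raises(ValueError):
            fret.ratio_stack(np.zeros((2, 4, 4)), np.ones((2, 4, 4)))

    def test_noiseless_roi_trace_matches_forward_model(self, small_phantom):
        """ROI ratio trace equals ratio(Ca(t)) from the generating model to
        better than 1%."""
        sched = SpikeSchedule([2.0], [1.0], duration=6.0)
        mv = _fret_movie(small_phantom, sched)
        donor, acc, _ = fret.split_and_register(mv, search_radius=2)
        rm = fret.ratio_stack(donor, acc, frame_interval=mv.frame_interval)
        trace = rm.roi_trace(small_phantom.somite_masks[0])
        _, ca, _ = somite_ca_traces(small_phantom, sched,
                                    TransientWaveform.cytosolic(),
                                    PropagationParams(), sampling=33.0,
                                    duration=6.0)
        expected = twitch_ratio_response(ca[0], TwitchModel(), dt=1 / 33.0)
        assert np.nanmax(np.abs(trace - expected) / expected) < 0.01


class TestBleaching:
    def test_constant_channel_reports_no_decline(self):
        out = fret.bleaching_summary(np.full(10, 5.0), np.arange(10.0))
        assert out["decline_percent"] == 0.0
        assert out["tau"] == np.inf

    def test_known_time_constant_recovered(self):
        tau = 4000.0
        t = np.linspace(0, 900, 40)
        out = fret.bleaching_summary(100 * np.exp(-t / tau), t, horizon=900.0)
        expected = 100 * (1 - np.exp(-900 / tau))
        assert out["decline_percent"] == pytest.approx(expected, abs=1.0)

    def test_default_simulator_channels_match_published_declines(self,
                                                                 small_phantom):
        """Event-free split-field movie with default bleaching loses ≈9%
        (donor) and ≈19% (acceptor) over 15 min."""
        sched = SpikeSchedule(np.empty(0), np.empty(0), duration=900.0)
        mv = _fret_movie(small_phantom, sched, rate=0.2,
                         bleach=BleachingModel())
        donor, acc, _ = fret.split_and_register(mv, search_radius=2)
        times = mv.times()
        trunk = small_phantom.trunk_mask
        d = fret.bleaching_summary(donor[:, trunk].mean(axis=1), times)
        a = fret.bleaching_summary(acc[:, trunk].mean(axis=1), times)
        assert d["decline_percent"] == pytest.approx(9.0, abs=0.5)
        assert a["decline_percent"] == pytest.approx(19.0, abs=0.5)

    def test_event_free_ratio_drifts_downward_under_bleaching(self,
                                                              small_phantom):
        sched = SpikeSchedule(np.empty(0), np.empty(0), duration=600.0)
        mv = _fret_movie(small_phantom, sched, rate=0.2,
                         bleach=BleachingModel())
        donor, acc, _ = fret.split_and_register(mv, search_radius=2)
        rm = fret.ratio_stack(donor, acc, frame_interval=mv.frame_interval)
        trace = rm.roi_trace(small_phantom.trunk_mask)
        assert trace[-1] < trace[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fret.bleaching_summary([1.0], [0.0])


def test_ratio_kinetics_match_forward_model_at_33hz(small_phantom):
    """Kinetic parameters from the noiseless ratio trace agree with the
    generating-waveform crossings within one frame interval."""
    from lumispark.detection import segment_events
    from lumispark.kinetics import event_kinetics

    rate = 33.0
    sched = SpikeSchedule([2.0], [1.0], duration=8.0)
    mv = _fret_movie(small_phantom, sched, rate=rate)
    donor, acc, _ = fret.split_and_register(mv, search_radius=2)
    rm = fret.ratio_stack(donor, acc, frame_interval=mv.frame_interval)
    trace = rm.roi_trace(small_phantom.somite_masks[0])
    base = np.median(trace)
    w = segment_events(trace, threshold=base + 0.05 * (trace.max() - base))[0]
    p = event_kinetics(trace, w, frame_interval=1 / rate)

    _, ca, _ = somite_ca_traces(small_phantom, sched,
                                TransientWaveform.cytosolic(),
                                PropagationParams(), sampling=10 * rate,
                                duration=8.0)
    dense = twitch_ratio_response(ca[0], TwitchModel(), dt=1 / (10 * rate))
    t = (np.arange(len(dense)) + 0.5) / (10 * rate)
    amp = dense.max() - dense.min()
    peak = np.argmax(dense)
    def crossing(level, side):
        x = dense - dense.min()
        if side == "up":
            return t[:peak][np.where(x[:peak] < level)[0][-1]]
        return t[peak:][np.where(x[peak:] < level)[0][0]]
    rise = crossing(0.9 * amp, "up") - crossing(0.1 * amp, "up")
    decay = crossing(0.1 * amp, "down") - crossing(0.9 * amp, "down")
    assert abs(p.rise_10_90 - rise) < 1 / rate
    assert abs(p.decay_90_10 - decay) < 1 / rate
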