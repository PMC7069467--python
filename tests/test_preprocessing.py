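import numpy as np
import pytest

from dynconn.errors import MontageError, ParameterError, PipelineError
from dynconn.preprocessing import (DEFAULT_NETWORK_MONTAGE, Recording,
                                   bandpass_fir, baseline_correct, epoch,
                                   reject_amplitude, rereference,
                                   select_channels)

RATE = 500.0


def sine_recording(freq_hz, seconds=100.0, labels=("Fz",)):
    t = np.arange(int(seconds * RATE)) / RATE
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (len(labels), 1))
    return Recording(data=data, rate=RATE, channel_labels=labels)


class TestBandpass:
    def test_passband_sine_amplitude_preserved(self):
        rec = bandpass_fir(sine_recording(10.0), 0.1, 30.0)
        mid = rec.data[0, 20000:-20000]
        assert abs(np.abs(mid).max() - 1.0) < 0.05

    def test_stopband_sine_attenuated_40db(self):
        rec = bandpass_fir(sine_recording(45.0), 0.1, 30.0)
        mid = rec.data[0, 20000:-20000]
        assert np.abs(mid).max() < 10 ** (-40 / 20)

    def test_zero_signal_stays_zero(self):
        rec = Recording(np.zeros((2, 30000)), RATE, ("a", "b"))
        out = bandpass_fir(rec, 1.0, 30.0, l_trans_hz=1.0)
        assert np.allclose(out.data, 0.0)

    @pytest.mark.parametrize("band", [(0.0, 30.0), (30.0, 0.1), (1.0, 300.0)])
    def test_band_outside_nyquist_rejected(self, band):
        with pytest.raises(ParameterError):
            bandpass_fir(sine_recording(10.0, seconds=10), *band)


class TestRereference:
    def test_zero_reference_is_identity(self):
        data = np.vstack([np.random.default_rng(0).standard_normal(100),
                          np.zeros(100), np.zeros(100)])
        rec = Recording(data, RATE, ("Cz", "TP9", "TP10"))
        assert np.allclose(rereference(rec).data[0], data[0])

    def test_common_mode_offset_removed(self):
        rec = Recording(np.full((4, 50), 7.3), RATE,
                        ("Fz", "Cz", "TP9", "TP10"))
        assert np.allclose(rereference(rec).data, 0.0)

    def test_three_channel_hand_arithmetic(self):
        rec = Recording(np.array([[1.0], [3.0], [10.0]]), RATE,
                        ("TP9", "TP10", "Cz"))
        assert rereference(rec).data[2, 0] == pytest.approx(10.0 - 2.0)

    def test_missing_reference_is_montage_error(self):
        rec = Recording(np.zeros((1, 10)), RATE, ("Cz",))
        with pytest.raises(MontageError):
            rereference(rec)


class TestEpoch:
    def events_recording(self, samples, events):
        rng = np.random.default_rng(3)
        return Recording(rng.standard_normal((2, samples)), RATE,
                         ("Fz", "Pz"), events=events)

    def test_one_trial_per_inbounds_event(self):
        rec = self.events_recording(20000, [(1000 + 700 * i, "standard")
                                            for i in range(10)])
        assert epoch(rec).n_trials == 10

    def test_event_at_start_dropped(self):
        events = [(0, "standard")] + [(1000 + 700 * i, "standard")
                                      for i in range(9)]
        rec = self.events_recording(20000, events)
        assert epoch(rec).n_trials == 9

    def test_sample_grid_600_samples_onset_at_100(self):
        rec = self.events_recording(3000, [(1000, "deviant")])
        ep = epoch(rec, (-200.0, 1000.0))
        assert ep.data.shape[2] == 600
        onset_idx = int(np.argmin(np.abs(ep.times_ms)))
        assert onset_idx == 100 and ep.times_ms[100] == 0.0
        assert np.allclose(ep.data[0, :, 100], rec.data[:, 1000])


class TestBaseline:
    def test_constant_trial_becomes_zero(self, epoch_factory):
        ep = epoch_factory(np.full((1, 2, 600), 5.0))
        assert np.allclose(baseline_correct(ep).data, 0.0)

    def test_idempotent_on_corrected_data(self, epoch_factory, rng):
        ep = baseline_correct(epoch_factory(rng.standard_normal((3, 2, 600))))
        again = baseline_correct(ep)
        assert np.allclose(again.data, ep.data)

    def test_mean_subtraction_hand_arithmetic(self, epoch_factory):
        # baseline samples cycle through {1, 2, 3} (mean 2); a post-stimulus
        # value of 10 must become 8
        data = np.zeros((1, 1, 600))
        data[0, 0, :99] = np.tile([1.0, 2.0, 3.0], 33)
        data[0, 0, 99] = 2.0
        data[0, 0, 300] = 10.0
        out = baseline_correct(epoch_factory(data))
        assert out.data[0, 0, 300] == pytest.approx(8.0)

    def test_baseline_mean_is_numerically_zero(self, epoch_factory, rng):
        ep = baseline_correct(epoch_factory(rng.standard_normal((8, 4, 600)) * 50))
        base = ep.data[:, :, :100].mean(axis=2)
        assert np.abs(base).max() < 1e-9 * 50

    def test_empty_baseline_window_rejected(self, epoch_factory, rng):
        ep = epoch_factory(rng.standard_normal((2, 2, 600)))
        with pytest.raises(ParameterError):
            baseline_correct(ep, (-200.0, -200.0))


class TestRejectAmplitude:
    def test_identical_trials_all_kept(self, epoch_factory):
        ep = epoch_factory(np.ones((5, 2, 600)))
        out, log = reject_amplitude(ep)
        assert out.n_trials == 5 and log["kept"].all()

    def test_planted_outlier_is_the_only_rejection(self, epoch_factory, rng):
        data = rng.standard_normal((21, 2, 600))
        data[13] *= 100.0
        out, log = reject_amplitude(epoch_factory(data), k=3.0)
        assert out.n_trials == 20
        assert not log.loc[13, "kept"]

    def test_infinite_k_rejects_nothing(self, epoch_factory, rng):
        ep = epoch_factory(rng.standard_normal((10, 2, 600)) * 100)
        out, _ = reject_amplitude(ep, k=np.inf)
        assert out.n_trials == 10

    def test_gaussian_trials_rarely_rejected(self, epoch_factory):
        rng = np.random.default_rng(99)
        ep = epoch_factory(rng.standard_normal((200, 4, 600)))
        out, _ = reject_amplitude(ep, k=3.0)
        assert (ep.n_trials - out.n_trials) / ep.n_trials < 0.05

    def test_all_rejected_is_pipeline_error(self, epoch_factory):
        # one huge outlier among two tiny trials -> mean+3SD can never
        # reject all, so force it with a negative k
        ep = epoch_factory(np.ones((3, 1, 600)) * [[[1]], [[2]], [[3]]])
        with pytest.raises(PipelineError):
            reject_amplitude(ep, k=-10.0)


class TestSelectChannels:
    def test_full_montage_subset_is_identity(self, epoch_factory, rng):
        ep = epoch_factory(rng.standard_normal((2, 3, 600)),
                           labels=("a", "b", "c"))
        out = select_channels(ep, ("a", "b", "c"))
        assert np.array_equal(out.data, ep.data)

    def test_27_label_default_subset_from_larger_montage(self, epoch_factory, rng):
        labels = DEFAULT_NETWORK_MONTAGE + ("TP9", "TP10", "Oz", "FCz")
        ep = epoch_factory(rng.standard_normal((2, len(labels), 600)),
                           labels=labels)
        out = select_channels(ep, DEFAULT_NETWORK_MONTAGE)
        assert out.data.shape[1] == 27
        assert out.channel_labels == DEFAULT_NETWORK_MONTAGE

    def test_duplicate_label_rejected(self, epoch_factory, rng):
        ep = epoch_factory(rng.standard_normal((1, 3, 600)),
                           labels=("a", "b", "c"))
        with pytest.raises(ParameterError):
            select_channels(ep, ("a", "a"))

    def test_unknown_label_is_montage_error(self, epoch_factory, rng):
        ep = epoch_factory(rng.standard_normal((1, 2, 600)), labels=("a", "b"))
        with pytest.raises(MontageError):
            select_channels(ep, ("a", "zz"))


def test_rereference_and_epoch_commute(toy_recording):
    """Re-referencing then epoching equals epoching then subtracting the
    epoched reference (linear operations on disjoint axes)."""
    a = epoch(rereference(toy_recording))
    b = epoch(toy_recording)
    epoched_ref = np.stack([
        toy_recording.data[[3, 4], s - 100:s + 500].mean(axis=0)
        for s, _ in toy_recording.events])
    assert np.allclose(a.data, b.data - epoched_ref[:, None, :], atol=1e-12)
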