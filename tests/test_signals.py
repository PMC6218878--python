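"""Signal-processing chain: detrending, R peaks, artifact removal, breaths."""

import numpy as np
import pytest
from scipy import signal as sps

from cardioresp import signals as sig
from cardioresp.synthetic import SignalScenario, generate_signals
from cardioresp.types import BeatSeries, SignalRecord


def _record(ecg=None, ip=None, fs=250.0):
    n = len(ecg) if ecg is not None else len(ip)
    return SignalRecord(
        ecg=ecg if ecg is not None else np.zeros(n),
        ip=ip if ip is not None else np.zeros(n),
        fs=fs,
    )


class TestDetrendEcg:
    def test_constant_becomes_zero(self):
        out = sig.detrend_ecg(_record(ecg=np.full(5000, 5.0)))
        assert np.allclose(out.ecg, 0.0)

    def test_linear_drift_removed_under_spikes(self):
        fs, dur = 250.0, 60.0
        t = np.arange(int(dur * fs)) / fs
        drift = 10.0 * t / dur
        spikes = np.zeros_like(t)
        spikes[::250] = 3.0
        out = sig.detrend_ecg(_record(ecg=spikes + drift, fs=fs))
        # oracle: the known drift; residual baseline between spikes is tiny
        baseline = out.ecg[(np.arange(len(t)) % 250) > 30]
        assert np.ptp(baseline) < 0.1

    def test_empty_channel_rejected(self):
        with pytest.raises(ValueError):
            sig.detrend_ecg(_record(ecg=np.array([])))

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sig.detrend_ecg(_record(ecg=np.zeros(50)))


class TestDetectRPeaks:
    def test_clean_sixty_bpm(self, degenerate_recording):
        record, truth = degenerate_recording
        beats = sig.detect_r_peaks(sig.detrend_ecg(record))
        assert abs(beats.n_beats - len(truth.events["r_peak_times"])) <= 1
        assert np.all(np.abs(beats.rr_intervals - 1000.0) <= 4.0)

    def test_flat_signal_flagged_not_raised(self):
        beats = sig.detect_r_peaks(_record(ecg=np.zeros(250 * 30)))
        assert beats.flagged and beats.n_beats == 0

    def test_noisy_ecg_recall(self):
        record, truth = generate_signals(
            SignalScenario(duration_s=120.0, mean_hr=70.0, rmssd_target=40.0,
                           noise_sd=0.0, seed=9)
        )
        sig_pow = np.mean(record.ecg ** 2)
        rng = np.random.default_rng(1)
        noisy = record.replace(
            ecg=record.ecg + rng.normal(0, np.sqrt(sig_pow / 10), record.n_samples)
        )  # SNR 10 dB
        beats = sig.detect_r_peaks(sig.detrend_ecg(noisy))
        true_times = truth.events["r_peak_times"]
        matched = sum(
            np.min(np.abs(beats.r_peak_times - t)) < 0.02 for t in true_times
        )
        assert matched / len(true_times) >= 0.99

    def test_zero_noise_recall_and_precision(self, typical_recording):
        record, truth = typical_recording
        beats = sig.detect_r_peaks(sig.detrend_ecg(record))
        true_times = truth.events["r_peak_times"]
        assert abs(beats.n_beats - len(true_times)) <= 1
        matched = sum(
            np.min(np.abs(beats.r_peak_times - t)) < 0.02 for t in true_times
        )
        assert matched >= len(true_times) - 1


class TestCardiacRemoval:
    def test_artifact_band_reduced_breath_band_preserved(self):
        fs, dur = 250.0, 180.0
        n = int(fs * dur)
        t = np.arange(n) / fs
        rng = np.random.default_rng(0)
        breath = np.sin(2 * np.pi * 0.25 * t)
        beat_times = np.cumsum(0.95 + rng.normal(0, 0.04, 250))
        beat_times = beat_times[beat_times < dur - 1]
        artifact = np.zeros(n)
        for bt in beat_times:
            artifact += 0.2 * np.exp(-(((t - bt) / 0.05) ** 2))
        record = _record(ip=breath + artifact, fs=fs)
        out = sig.remove_cardiac_component(record, BeatSeries(beat_times))

        def bandpower(x, lo, hi):
            f, p = sps.welch(x, fs, nperseg=8192)
            m = (f >= lo) & (f <= hi)
            return np.trapezoid(p[m], f[m])

        reduction = 10 * np.log10(
            bandpower(record.ip, 0.8, 2.0) / bandpower(out.ip, 0.8, 2.0)
        )
        breath_change = abs(10 * np.log10(
            bandpower(record.ip, 0.05, 0.5) / bandpower(out.ip, 0.05, 0.5)
        ))
        assert reduction >= 10.0
        assert breath_change < 1.0

    def test_zero_artifact_output_close_to_input(self):
        record, truth = generate_signals(
            SignalScenario(cardiac_artifact_gain=0.0, noise_sd=0.0, seed=2)
        )
        out = sig.remove_cardiac_component(
            record, BeatSeries(truth.events["r_peak_times"])
        )
        assert np.max(np.abs(out.ip - record.ip)) < 0.01 * np.std(record.ip)

    def test_empty_beats_returns_input_with_flag(self):
        record = _record(ip=np.sin(np.arange(2500) / 100.0))
        out = sig.remove_cardiac_component(record, BeatSeries(np.array([])))
        assert np.array_equal(out.ip, record.ip)
        assert "skipped" in out.flags["cardiac_removal"]


class TestSmoothIp:
    def test_constant_unchanged(self):
        out = sig.smooth_ip(_record(ip=np.full(1000, 2.5)))
        assert np.allclose(out.ip, 2.5)

    def test_impulse_becomes_plateau(self):
        x = np.zeros(2500)
        x[1200] = 1.0
        out = sig.smooth_ip(_record(ip=x, fs=250.0))
        assert np.isclose(out.ip.max(), 1.0 / 100)
        assert np.sum(np.isclose(out.ip, 1.0 / 100)) == 100

    def test_sine_attenuation_matches_moving_average_response(self):
        t = np.arange(60 * 250) / 250.0
        out = sig.smooth_ip(_record(ip=np.sin(2 * np.pi * 0.25 * t), fs=250.0))
        mid = out.ip[2500:-2500]
        expected = abs(np.sinc(0.25 * 0.4))  # |sin(pi f T)/(pi f T)|
        assert np.max(np.abs(mid)) == pytest.approx(expected, rel=0.01)


class TestDelimitBreaths:
    def test_sine_ip_timing_and_amplitudes(self, sine_ip_record):
        breaths = sig.delimit_breaths(sine_ip_record)
        assert 13 <= breaths.n_breaths <= 15
        assert np.all(np.abs(breaths.ins_durations - 2.0) <= 0.02)
        assert np.all(np.abs(breaths.exp_durations - 2.0) <= 0.02)
        amps = np.concatenate([breaths.ins_amplitudes, breaths.exp_amplitudes])
        assert np.ptp(amps) / np.mean(amps) < 0.01

    def test_flat_ip_rejected(self):
        with pytest.raises(ValueError, match="insufficient respiratory"):
            sig.delimit_breaths(_record(ip=np.zeros(250 * 60)))

    def test_small_lobe_rejected_by_adaptive_threshold(self):
        fs = 250.0
        t = np.arange(int(40 * fs)) / fs
        ip = np.sin(2 * np.pi * 0.25 * t)
        # shrink one full breath (4 s) to 1/20 amplitude: its flow lobes fall
        # below 20% of the running median lobe area and must be merged away
        k = (t >= 16.0) & (t < 20.0)
        ip[k] *= 0.05
        normal = sig.delimit_breaths(_record(ip=np.sin(2 * np.pi * 0.25 * t), fs=fs))
        pruned = sig.delimit_breaths(_record(ip=ip, fs=fs))
        assert pruned.n_breaths == normal.n_breaths - 1

    def test_offset_and_scale_invariance(self, sine_ip_record):
        base = sig.delimit_breaths(sine_ip_record)
        scaled = sig.delimit_breaths(
            sine_ip_record.replace(ip=5.0 + 3.0 * sine_ip_record.ip)
        )
        assert scaled.n_breaths == base.n_breaths
        # timings unchanged within one sample of quantization
        assert np.max(np.abs(scaled.ins_onsets - base.ins_onsets)) <= 1.0 / 250 + 1e-12
        # amplitudes scale proportionally (tiny jitter from the one-sample
        # shift of an onset at a floating-point zero crossing)
        assert np.allclose(scaled.ins_amplitudes, 3.0 * base.ins_amplitudes, rtol=1e-4)

    def test_onsets_alternate_and_lie_in_range(self, typical_recording):
        record, _ = typical_recording
        smoothed = sig.smooth_ip(record)
        breaths = sig.delimit_breaths(smoothed)
        assert np.all(breaths.ins_onsets < breaths.exp_onsets)
        assert np.all(breaths.exp_onsets[:-1] < breaths.ins_onsets[1:])
        assert breaths.ins_onsets.min() >= 0
        assert breaths.exp_onsets.max() <= record.duration_s
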