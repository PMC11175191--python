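"""Ingestion, filtering, epoching, scaling and noise calibration."""

from __future__ import annotations

import numpy as np
import pytest

from fuzzygcn.data import EEGRecording, EpochSet
from fuzzygcn.preprocess import (bandpass_butterworth,
                                 butterworth_bandpass_gain, epoch_split,
                                 inject_noise, minmax_normalize, notch_filter,
                                 read_recording, select_channels)

from conftest import write_minimal_edf


def make_rec(data, names=None, fs=500.0, label=0):
    names = names or [f"C{i}" for i in range(len(data))]
    return EEGRecording(data=np.asarray(data, dtype=float),
                        channel_names=names, fs=fs, label=label,
                        subject_id="S01")


def sine(freq, fs, n, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestReadRecording:
    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "rec.csv"
        rows = ["Fz,Cz,Pz,O1,O2"]
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((100, 5))
        rows += [",".join(f"{v:.6f}" for v in row) for row in vals]
        path.write_text("\n".join(rows))
        rec = read_recording(str(path), format="csv", fs=500.0)
        assert rec.data.shape == (5, 100)
        assert rec.channel_names == ["Fz", "Cz", "Pz", "O1", "O2"]
        assert rec.fs == 500.0
        np.testing.assert_allclose(rec.data, vals.T, atol=1e-6)

    def test_csv_requires_fs(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("A,B\n1,2\n")
        with pytest.raises(ValueError, match="sampling rate"):
            read_recording(str(path), format="csv")

    def test_csv_header_mismatch(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("A,B,C,D,E\n1,2,3,4\n")
        with pytest.raises(ValueError, match="header"):
            read_recording(str(path), format="csv", fs=100.0)

    def test_edf_header_names_and_rate(self, tmp_path):
        path = tmp_path / "rec.edf"
        rng = np.random.default_rng(3)
        names = [f"EEG{i}" for i in range(16)]
        data = 20.0 * rng.standard_normal((16, 1000))  # inside +/-200 uV
        write_minimal_edf(path, data, names, fs=500.0)
        rec = read_recording(str(path), format="edf")
        assert rec.n_channels == 16
        assert rec.fs == 500.0
        assert [n.replace("EEG ", "EEG") for n in rec.channel_names] == names \
            or rec.channel_names == names
        # int16 quantization in a +/-200 uV range: ~6e-3 uV resolution
        np.testing.assert_allclose(rec.data, data, atol=2e-2)

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_recording("x", format="mat")


class TestSelectChannels:
    def test_reduction_and_order(self):
        names = [f"ch{i}" for i in range(11)] + ["Fz", "Cz", "Pz", "O1", "O2"]
        rec = make_rec(np.arange(16)[:, None] * np.ones((16, 10)), names)
        out = select_channels(rec, ["Fz", "Cz", "Pz", "O1", "O2"])
        assert out.channel_names == ["Fz", "Cz", "Pz", "O1", "O2"]
        assert out.data.shape == (5, 10)
        np.testing.assert_array_equal(out.data[:, 0], [11, 12, 13, 14, 15])
        assert out.fs == rec.fs and out.label == rec.label

    def test_identity(self):
        rec = make_rec(np.random.default_rng(0).standard_normal((3, 20)),
                       ["A", "B", "C"])
        out = select_channels(rec, ["A", "B", "C"])
        np.testing.assert_array_equal(out.data, rec.data)

    def test_case_insensitive(self):
        rec = make_rec(np.ones((2, 5)), ["Fz", "Cz"])
        out = select_channels(rec, ["FZ", "cz"])
        assert out.channel_names == ["Fz", "Cz"]

    def test_missing_channel_lists_available(self):
        rec = make_rec(np.ones((2, 5)), ["Fz", "Cz"])
        with pytest.raises(KeyError, match="Cz"):
            select_channels(rec, ["Fz", "XX"])


class TestFilters:
    fs = 500.0

    def test_notch_kills_mains(self):
        rec = make_rec([sine(50, self.fs, 5000)], fs=self.fs)
        out = notch_filter(rec, f0=50.0)
        rms_in = np.sqrt(np.mean(rec.data ** 2))
        rms_out = np.sqrt(np.mean(out.data[:, 500:-500] ** 2))
        assert rms_out <= 0.01 * rms_in

    def test_notch_preserves_distant_tone(self):
        rec = make_rec([sine(10, self.fs, 5000)], fs=self.fs)
        out = notch_filter(rec, f0=50.0)
        # FFT amplitude at 10 Hz before and after
        spec_in = np.abs(np.fft.rfft(rec.data[0]))
        spec_out = np.abs(np.fft.rfft(out.data[0]))
        k = int(10 * 5000 / self.fs)
        assert abs(spec_out[k] / spec_in[k] - 1.0) < 0.02

    def test_notch_above_nyquist_rejected(self):
        rec = make_rec(np.ones((1, 100)), fs=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            notch_filter(rec, f0=50.0)

    def test_bandpass_passband_gain(self):
        gain = butterworth_bandpass_gain(10.0, 0.05, 60.0, 2, self.fs)
        rec = make_rec([sine(10, self.fs, 10000)], fs=self.fs)
        out = bandpass_butterworth(rec)
        spec_in = np.abs(np.fft.rfft(rec.data[0]))
        spec_out = np.abs(np.fft.rfft(out.data[0]))
        k = int(10 * 10000 / self.fs)
        measured = spec_out[k] / spec_in[k]
        assert 0.95 <= measured <= 1.05
        assert abs(measured - gain) < 0.02

    def test_bandpass_stopband(self):
        # measure at the tone's FFT bin: the 0.05 Hz high-pass edge leaves a
        # long low-frequency transient that a time-domain peak would pick up
        rec = make_rec([sine(120, self.fs, 10000)], fs=self.fs)
        out = bandpass_butterworth(rec)
        spec_in = np.abs(np.fft.rfft(rec.data[0]))
        spec_out = np.abs(np.fft.rfft(out.data[0]))
        k = int(120 * 10000 / self.fs)
        measured = spec_out[k] / spec_in[k]
        gain = butterworth_bandpass_gain(120.0, 0.05, 60.0, 2, self.fs)
        assert measured < 0.5
        assert abs(measured - gain) < 0.02

    @pytest.mark.parametrize("filt", [
        lambda r: notch_filter(r, 50.0),
        lambda r: bandpass_butterworth(r),
    ])
    def test_zero_in_zero_out(self, filt):
        rec = make_rec(np.zeros((2, 1000)), fs=self.fs)
        np.testing.assert_array_equal(filt(rec).data, 0.0)

    @pytest.mark.parametrize("filt", [
        lambda r: notch_filter(r, 50.0),
        lambda r: bandpass_butterworth(r),
    ])
    def test_linearity(self, filt, rng):
        x = rng.standard_normal((1, 2000))
        y = rng.standard_normal((1, 2000))
        a, b = 2.5, -1.3
        fx = filt(make_rec(x, fs=self.fs)).data
        fy = filt(make_rec(y, fs=self.fs)).data
        fxy = filt(make_rec(a * x + b * y, fs=self.fs)).data
        np.testing.assert_allclose(fxy, a * fx + b * fy, atol=1e-9)

    def test_zero_phase_preserves_peak_latency(self):
        n = 2000
        pulse = np.exp(-0.5 * ((np.arange(n) - 1000) / 30.0) ** 2)
        out = bandpass_butterworth(make_rec([pulse], fs=self.fs),
                                   low=0.5, high=60.0)
        assert abs(int(np.argmax(out.data[0])) - 1000) <= 1

    def test_invalid_band_edges(self):
        rec = make_rec(np.ones((1, 100)), fs=100.0)
        with pytest.raises(ValueError, match="band edges"):
            bandpass_butterworth(rec, low=60.0, high=10.0)


class TestEpochSplit:
    def test_thirty_seconds_at_500hz_is_one_15000_sample_trial(self):
        rec = make_rec(np.random.default_rng(0).standard_normal((2, 15000)),
                       fs=500.0)
        es = epoch_split(rec, epoch_len=15000, stride=15000)
        assert es.n_trials == 1
        assert es.epoch_len == 15000
        assert es.epoch_len == int(30 * 500)

    def test_sliding_window_count(self):
        rec = make_rec(np.zeros((1, 15000)), fs=500.0)
        es = epoch_split(rec, epoch_len=1000, stride=500)
        assert es.n_trials == (15000 - 1000) // 500 + 1 == 29

    def test_single_full_epoch_identity(self):
        data = np.random.default_rng(0).standard_normal((3, 777))
        rec = make_rec(data, fs=100.0)
        es = epoch_split(rec, epoch_len=777, stride=777)
        assert es.n_trials == 1
        np.testing.assert_array_equal(es.epochs[0], data)

    def test_label_and_subject_inherited(self):
        rec = make_rec(np.zeros((1, 100)), fs=100.0)
        es = epoch_split(rec, epoch_len=50, stride=25)
        assert np.all(es.labels == 0)
        assert all(s == "S01" for s in es.subject_ids)

    def test_too_long_epoch_rejected(self):
        rec = make_rec(np.zeros((1, 100)), fs=100.0)
        with pytest.raises(ValueError, match="exceeds"):
            epoch_split(rec, epoch_len=101)


class TestMinMaxNormalize:
    def make_set(self, arr):
        arr = np.asarray(arr, dtype=float)
        return EpochSet(epochs=arr, labels=np.zeros(arr.shape[0], dtype=int),
                        fs=100.0)

    def test_formula(self):
        es = self.make_set([[[2.0, 4.0, 6.0]]])
        out = minmax_normalize(es)
        np.testing.assert_allclose(out.epochs[0, 0], [0.0, 0.5, 1.0])

    def test_constant_channel_maps_to_zero(self):
        es = self.make_set([[[3.0, 3.0, 3.0]]])
        np.testing.assert_array_equal(minmax_normalize(es).epochs, 0.0)

    def test_idempotent_when_bounds_attained(self, rng):
        es = self.make_set(rng.standard_normal((4, 3, 50)))
        once = minmax_normalize(es)
        twice = minmax_normalize(once)
        np.testing.assert_allclose(twice.epochs, once.epochs, atol=1e-15)
        assert once.epochs.min() == 0.0 and once.epochs.max() == 1.0


class TestInjectNoise:
    def make_set(self, rng, n_trials=5, n=10_000):
        return EpochSet(epochs=rng.standard_normal((n_trials, 2, n)),
                        labels=np.zeros(n_trials, dtype=int), fs=500.0)

    def test_infinite_snr_is_identity(self, rng):
        es = self.make_set(rng)
        out = inject_noise(es, float("inf"), seed=0)
        np.testing.assert_array_equal(out.epochs, es.epochs)

    def test_zero_db_noise_variance(self, rng):
        es = self.make_set(rng, n_trials=3, n=10_000)
        out = inject_noise(es, 0.0, seed=42)
        for t in range(es.n_trials):
            sig_power = np.mean(es.epochs[t] ** 2)
            noise_var = np.var(out.epochs[t] - es.epochs[t])
            assert abs(noise_var / sig_power - 1.0) < 0.05

    def test_seed_determinism(self, rng):
        es = self.make_set(rng)
        a = inject_noise(es, 5.0, seed=9)
        b = inject_noise(es, 5.0, seed=9)
        np.testing.assert_array_equal(a.epochs, b.epochs)

    def test_achieved_snr_within_tenth_db(self, rng):
        es = EpochSet(epochs=rng.standard_normal((2, 1, 100_000)),
                      labels=np.zeros(2, dtype=int), fs=500.0)
        for snr in (0.0, 10.0):
            out = inject_noise(es, snr, seed=3)
            noise = out.epochs - es.epochs
            achieved = 10 * np.log10(np.mean(es.epochs ** 2)
                                     / np.mean(noise ** 2))
            assert abs(achieved - snr) < 0.1
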