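"""EEG ingestion and preprocessing.

The pipeline mirrors standard practice for scalp EEG classification: read a
recording (EDF or delimited text), keep a reduced 10-20 montage (Fz, Cz, Pz,
O1, O2 by default), remove mains interference with a notch filter, band-limit
with a 2nd-order Butterworth filter (0.05-60 Hz), cut the continuous signal
into fixed-length trials, and scale each trial's channels into [0, 1].

All filters are applied forward-backward (zero-phase), so the effective
magnitude response is the square of the designed one and peak latencies are
preserved. Calibrated white-noise injection for robustness sweeps lives here
too: noise variance is set per trial from the trial's own mean-square power
and the requested SNR in dB.
"""

from __future__ import annotations

import csv
import math

import numpy as np
from scipy import signal

from .data import EEGRecording, EpochSet

#: channels kept by default, after the montage-reduction step
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "O1", "O2")


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_recording(path: str, format: str = "csv", fs: float | None = None,
                   label: int | None = None,
                   subject_id: str = "") -> EEGRecording:
    """Read a continuous recording from ``path``.

    Parameters
    ----------
    path:
        Input file. ``format="edf"`` reads a European Data Format file
        (channel names and sampling rate from the header); ``format="csv"``
        reads delimited text with one column per channel, a header row of
        channel names and one sample per row.
    fs:
        Required for CSV (the format carries no rate); ignored for EDF.
    label, subject_id:
        Optional trial metadata attached to the recording.
    """
    if format == "edf":
        return _read_edf(path, label=label, subject_id=subject_id)
    if format == "csv":
        if fs is None:
            raise ValueError("CSV input carries no sampling rate; pass fs=")
        return _read_csv(path, fs=fs, label=label, subject_id=subject_id)
    raise ValueError(f"unknown format {format!r}; expected 'edf' or 'csv'")


def _read_csv(path: str, fs: float, label: int | None,
              subject_id: str) -> EEGRecording:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    data_rows = []
    for i, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise ValueError(
                f"{path}:{i}: row has {len(row)} values but header names "
                f"{len(header)} channels")
        try:
            data_rows.append([float(v) for v in row])
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: non-numeric value") from exc
    if not data_rows:
        raise ValueError(f"{path}: no data rows")
    data = np.asarray(data_rows, dtype=np.float64).T  # -> channels x samples
    return EEGRecording(data=data, channel_names=header, fs=fs,
                        label=label, subject_id=subject_id)


def _read_edf(path: str, label: int | None, subject_id: str) -> EEGRecording:
    import mne  # deferred: mne import is slow and only needed for EDF

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; store microvolts
    return EEGRecording(data=data, channel_names=list(raw.ch_names),
                        fs=float(raw.info["sfreq"]),
                        label=label, subject_id=subject_id)


# ---------------------------------------------------------------------------
# montage reduction
# ---------------------------------------------------------------------------

def select_channels(rec: EEGRecording,
                    keep: list[str] | tuple[str, ...] = DEFAULT_CHANNELS
                    ) -> EEGRecording:
    """Keep (and reorder to) the named channels.

    Matching is case-insensitive, so "FZ", "fz" and "Fz" all address the same
    electrode; the output rows follow the order of ``keep``.
    """
    lookup = {name.lower(): i for i, name in enumerate(rec.channel_names)}
    idx = []
    for name in keep:
        if name.lower() not in lookup:
            raise KeyError(
                f"channel {name!r} not present; available: "
                f"{', '.join(rec.channel_names)}")
        idx.append(lookup[name.lower()])
    return EEGRecording(data=rec.data[idx].copy(),
                        channel_names=[rec.channel_names[i] for i in idx],
                        fs=rec.fs, label=rec.label, subject_id=rec.subject_id)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def notch_filter(rec: EEGRecording, f0: float = 50.0,
                 q: float = 30.0) -> EEGRecording:
    """Zero-phase IIR notch at ``f0`` Hz (mains interference removal)."""
    if not f0 < rec.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz is not below Nyquist "
                         f"({rec.fs / 2} Hz)")
    b, a = signal.iirnotch(f0, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return EEGRecording(data=out, channel_names=list(rec.channel_names),
                        fs=rec.fs, label=rec.label, subject_id=rec.subject_id)


def bandpass_butterworth(rec: EEGRecording, low: float = 0.05,
                         high: float = 60.0, order: int = 2) -> EEGRecording:
    """Zero-phase Butterworth band-pass (default 0.05-60 Hz, 2nd order)."""
    nyq = rec.fs / 2
    if not (0 < low < high < nyq):
        raise ValueError(
            f"invalid band edges ({low}, {high}) for fs={rec.fs}: require "
            f"0 < low < high < {nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(data=out, channel_names=list(rec.channel_names),
                        fs=rec.fs, label=rec.label, subject_id=rec.subject_id)


def butterworth_bandpass_gain(freq: float, low: float, high: float,
                              order: int, fs: float) -> float:
    """Magnitude response of the zero-phase band-pass at ``freq`` Hz.

    Forward-backward filtering squares the single-pass magnitude; this is the
    analytic reference the filtering tests check against.
    """
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs,
                        output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)


# ---------------------------------------------------------------------------
# epoching and scaling
# ---------------------------------------------------------------------------

def epoch_split(rec: EEGRecording, epoch_len: int,
                stride: int | None = None) -> EpochSet:
    """Cut the recording into sliding windows of ``epoch_len`` samples.

    The trailing partial window is discarded. Each epoch inherits the
    recording's label and subject id. ``stride`` defaults to ``epoch_len``
    (non-overlapping windows).
    """
    if stride is None:
        stride = epoch_len
    if epoch_len > rec.n_samples:
        raise ValueError(f"epoch_len={epoch_len} exceeds recording length "
                         f"{rec.n_samples}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n_epochs = (rec.n_samples - epoch_len) // stride + 1
    epochs = np.stack([rec.data[:, i * stride:i * stride + epoch_len]
                       for i in range(n_epochs)])
    label = rec.label if rec.label is not None else -1
    return EpochSet(
        epochs=epochs,
        labels=np.full(n_epochs, label, dtype=np.int64),
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        subject_ids=np.array([rec.subject_id] * n_epochs, dtype=object),
    )


def minmax_normalize(es: EpochSet) -> EpochSet:
    """Scale each trial's channels independently into [0, 1].

    x' = (x - min) / (max - min), per epoch and per channel. A constant
    channel has zero range and maps to all-zeros by convention.
    """
    lo = es.epochs.min(axis=2, keepdims=True)
    hi = es.epochs.max(axis=2, keepdims=True)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    out = np.where(rng > 0, (es.epochs - lo) / safe, 0.0)
    res = es.copy()
    res.epochs = out
    return res


# ---------------------------------------------------------------------------
# calibrated noise injection
# ---------------------------------------------------------------------------

def inject_noise(es: EpochSet, snr_db: float, seed: int) -> EpochSet:
    """Add zero-mean Gaussian white noise at a per-trial calibrated SNR.

    For each trial, noise variance = (mean square of the trial) /
    10^(snr_db/10). ``snr_db = inf`` returns an identical copy (zero noise
    power). Deterministic under ``seed``.
    """
    out = es.copy()
    if math.isinf(snr_db) and snr_db > 0:
        return out
    rng = np.random.default_rng(seed)
    power = np.mean(es.epochs ** 2, axis=(1, 2))  # per trial
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    noise = rng.standard_normal(es.epochs.shape)
    out.epochs = es.epochs + sigma[:, None, None] * noise
    return out
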