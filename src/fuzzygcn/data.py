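"""Core containers for multichannel EEG: continuous recordings and epoched trials.

An :class:`EEGRecording` is a continuous channels x samples matrix with 10-20
channel names and a sampling rate; an :class:`EpochSet` is a stack of
fixed-length labeled trials (trials x channels x samples) as produced by
epoching and consumed by the graph builder, the GAN and the classifier.

Labels are binary throughout: 0 = truth, 1 = lie.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

#: canonical label coding used across the package
LABEL_NAMES = ("truth", "lie")

#: provenance codes for trials
PROVENANCE_REAL = "real"
PROVENANCE_GAN = "gan"


@dataclass
class EEGRecording:
    """A continuous multichannel EEG recording.

    Attributes
    ----------
    data:
        ``(n_channels, n_samples)`` float array, microvolts.
    channel_names:
        Ordered 10-20 electrode labels, one per data row.
    fs:
        Sampling rate in Hz.
    label:
        ``0`` (truth), ``1`` (lie) or ``None`` when unlabeled.
    subject_id:
        Opaque subject identifier.
    """

    data: np.ndarray
    channel_names: list[str]
    fs: float
    label: int | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names were given"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or Inf samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(),
                       channel_names=list(self.channel_names))


@dataclass
class EpochSet:
    """Labeled fixed-length trials: a ``(n_trials, n_channels, n_samples)`` tensor.

    ``provenance`` records, per trial, the originating subject and whether the
    trial is a real recording segment or a GAN-synthesized one; augmentation
    and the train/val/test splitter rely on it to keep synthetic trials out of
    evaluation partitions.
    """

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_ids: np.ndarray | None = None
    sources: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (trials, channels, samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal trial count")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.epochs.shape[1])]
        if self.epochs.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must equal channel count")
        n = self.epochs.shape[0]
        if self.subject_ids is None:
            self.subject_ids = np.array([""] * n, dtype=object)
        else:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.sources is None:
            self.sources = np.array([PROVENANCE_REAL] * n, dtype=object)
        else:
            self.sources = np.asarray(self.sources, dtype=object)
        if len(self.subject_ids) != n or len(self.sources) != n:
            raise ValueError("provenance arrays must match trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]

    def subset(self, idx: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to trial indices ``idx``."""
        idx = np.asarray(idx)
        return EpochSet(
            epochs=self.epochs[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            subject_ids=self.subject_ids[idx],
            sources=self.sources[idx],
        )

    def copy(self) -> "EpochSet":
        return self.subset(np.arange(self.n_trials))

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def concatenate(sets: list[EpochSet]) -> EpochSet:
    """Stack several EpochSets (same channel layout, fs and epoch length)."""
    first = sets[0]
    for es in sets[1:]:
        if es.channel_names != first.channel_names:
            raise ValueError("channel layouts differ")
        if es.fs != first.fs or es.epoch_len != first.epoch_len:
            raise ValueError("sampling rate / epoch length differ")
    return EpochSet(
        epochs=np.concatenate([es.epochs for es in sets], axis=0),
        labels=np.concatenate([es.labels for es in sets]),
        fs=first.fs,
        channel_names=list(first.channel_names),
        subject_ids=np.concatenate([es.subject_ids for es in sets]),
        sources=np.concatenate([es.sources for es in sets]),
    )


def save_epochs(es: EpochSet, path: str) -> None:
    """Serialize an EpochSet to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=es.epochs)
        f.create_dataset("labels", data=es.labels)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("subject_ids",
                         data=np.asarray(es.subject_ids, dtype=str_dt))
        f.create_dataset("sources", data=np.asarray(es.sources, dtype=str_dt))
        f.attrs["fs"] = es.fs
        f.attrs["epoch_len"] = es.epoch_len
        f.attrs["channel_names"] = list(es.channel_names)


def load_epochs(path: str) -> EpochSet:
    """Load an EpochSet from :func:`save_epochs` output."""
    with h5py.File(path, "r") as f:
        return EpochSet(
            epochs=f["epochs"][:],
            labels=f["labels"][:],
            fs=float(f.attrs["fs"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            subject_ids=np.array([s.decode() if isinstance(s, bytes) else str(s)
                                  for s in f["subject_ids"][:]], dtype=object),
            sources=np.array([s.decode() if isinstance(s, bytes) else str(s)
                              for s in f["sources"][:]], dtype=object),
        )
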