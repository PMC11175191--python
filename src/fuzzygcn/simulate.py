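"""Seeded two-class synthetic EEG generator.

The generator emulates the statistical structure a two-condition EEG
classification study rests on, without any biophysical head modeling. Each
channel is a unit-variance mixture of

* band-limited stochastic oscillators — AR(2) resonators centered on the
  classic delta/theta/alpha/beta bands, with class- and channel-dependent
  amplitudes (posterior alpha emphasis, frontal beta emphasis),
* 1/f "pink" background activity and white sensor noise,
* shared oscillator sources injected into coupled channel pairs, so that
  inter-channel Pearson correlation is controlled per pair and per class.

The two classes ("truth" = 0, "lie" = 1) differ in alpha-vs-beta band power
and in which channel pairs are strongly coupled; ``effect_size`` scales every
class difference (0 makes the classes distributionally identical). The
coupling coefficient c of a pair is mapped to a mixing weight
lambda = c / sqrt(1 - c^2), which for a channel in a single pair yields an
expected correlation of exactly c^2.

Everything is reproducible from an integer seed; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .data import EpochSet

#: default 10-20 montage of the study layout
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "O1", "O2")

#: band name -> (center Hz, bandwidth Hz)
DEFAULT_BANDS = {
    "delta": (2.0, 1.5),
    "theta": (6.0, 2.0),
    "alpha": (10.0, 2.5),
    "beta": (20.0, 5.0),
}

#: per-channel gain profiles (posterior alpha, frontal beta)
_ALPHA_GAIN = {"Fz": 0.6, "Cz": 0.8, "Pz": 1.0, "O1": 1.1, "O2": 1.1}
_BETA_GAIN = {"Fz": 1.1, "Cz": 1.0, "Pz": 0.8, "O1": 0.7, "O2": 0.7}


def _default_band_amps() -> dict:
    # class -> band -> amplitude; alpha/beta carry the class contrast
    return {
        0: {"delta": 0.3, "theta": 0.4, "alpha": 1.2, "beta": 0.4},
        1: {"delta": 0.3, "theta": 0.4, "alpha": 0.4, "beta": 1.1},
    }


def _default_coupling() -> dict:
    # class -> {(chan, chan): coupling in [0, 1)}
    return {
        0: {("Pz", "O1"): 0.8, ("Fz", "Cz"): 0.3, ("O1", "O2"): 0.7},
        1: {("Pz", "O1"): 0.3, ("Fz", "Cz"): 0.8, ("O1", "O2"): 0.7},
    }


@dataclass
class SimSpec:
    """Study-condition parameters of the synthetic dataset."""

    n_subjects: int = 20
    trials_per_class: int = 200
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    fs: float = 500.0
    epoch_len: int = 1000
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    band_amps: dict = field(default_factory=_default_band_amps)
    coupling: dict = field(default_factory=_default_coupling)
    pink_amp: float = 0.3
    white_amp: float = 0.2
    effect_size: float = 1.0
    subject_gain_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        nyq = self.fs / 2
        for name, (f0, bw) in self.bands.items():
            if not 0 < f0 < nyq:
                raise ValueError(f"band {name}: center {f0} outside (0, {nyq})")
        for cls in self.coupling.values():
            for (a, b), c in cls.items():
                if a not in self.channel_names or b not in self.channel_names:
                    raise ValueError(f"coupling names unknown: {(a, b)}")
                if not 0 <= c < 1:
                    raise ValueError(f"coupling {c} outside [0, 1)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def effective_band_amps(self) -> dict:
        """Class band amplitudes after effect_size scaling of the contrast."""
        out: dict = {}
        for band in self.bands:
            a0 = self.band_amps[0][band]
            a1 = self.band_amps[1][band]
            mid, half = (a0 + a1) / 2, (a0 - a1) / 2
            out.setdefault(0, {})[band] = mid + self.effect_size * half
            out.setdefault(1, {})[band] = mid - self.effect_size * half
        return out

    def effective_coupling(self) -> dict:
        """Class coupling maps after effect_size scaling of the contrast."""
        pairs = set(self.coupling[0]) | set(self.coupling[1])
        out: dict = {0: {}, 1: {}}
        for pair in pairs:
            c0 = self.coupling[0].get(pair, 0.0)
            c1 = self.coupling[1].get(pair, 0.0)
            mid, half = (c0 + c1) / 2, (c0 - c1) / 2
            out[0][pair] = float(np.clip(mid + self.effect_size * half, 0, 0.999))
            out[1][pair] = float(np.clip(mid - self.effect_size * half, 0, 0.999))
        return out

    def planted_edges(self) -> set[tuple[str, str]]:
        """Channel pairs coupled in the class-pooled data (the graph truth)."""
        return set(self.coupling[0]) | set(self.coupling[1])


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

_BURN_IN = 500


def ar2_oscillator(n: int, f0: float, bandwidth: float, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(2) resonator output at center frequency ``f0``."""
    r = np.exp(-np.pi * bandwidth / fs)
    omega = 2 * np.pi * f0 / fs
    a = [1.0, -2.0 * r * np.cos(omega), r * r]
    e = rng.standard_normal(n + _BURN_IN)
    y = sp_signal.lfilter([1.0], a, e)[_BURN_IN:]
    sd = y.std()
    return y / sd if sd > 0 else y


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    y = np.fft.irfft(spec * scale, n)
    sd = y.std()
    return y / sd if sd > 0 else y


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def simulate_dataset(spec: SimSpec, seed: int) -> EpochSet:
    """Generate a balanced, labeled EpochSet under the given study conditions."""
    rng = np.random.default_rng(seed)
    n_trials = 2 * spec.trials_per_class
    n_ch, n_samp = spec.n_channels, spec.epoch_len
    amps = spec.effective_band_amps()
    coupling = spec.effective_coupling()
    ch_index = {name: i for i, name in enumerate(spec.channel_names)}
    subj_gain = 1.0 + spec.subject_gain_sd * rng.standard_normal(spec.n_subjects)

    epochs = np.empty((n_trials, n_ch, n_samp))
    labels = np.empty(n_trials, dtype=np.int64)
    subjects = np.empty(n_trials, dtype=object)

    for t in range(n_trials):
        cls = t % 2
        subj = (t // 2) % spec.n_subjects
        labels[t] = cls
        subjects[t] = f"S{subj + 1:02d}"
        x = np.zeros((n_ch, n_samp))
        for i, name in enumerate(spec.channel_names):
            own = np.zeros(n_samp)
            for band, (f0, bw) in spec.bands.items():
                gain = 1.0
                if band == "alpha":
                    gain = _ALPHA_GAIN.get(name, 1.0)
                elif band == "beta":
                    gain = _BETA_GAIN.get(name, 1.0)
                own += amps[cls][band] * gain * ar2_oscillator(
                    n_samp, f0, bw, spec.fs, rng)
            own += spec.pink_amp * pink_noise(n_samp, rng)
            own += spec.white_amp * rng.standard_normal(n_samp)
            sd = own.std()
            x[i] = own / sd if sd > 0 else own
        # shared sources: broadband resonators injected into coupled pairs
        for (a, b), c in coupling[cls].items():
            if c <= 0:
                continue
            lam = c / np.sqrt(1.0 - c * c)
            shared = ar2_oscillator(n_samp, 10.0, 8.0, spec.fs, rng)
            x[ch_index[a]] += lam * shared
            x[ch_index[b]] += lam * shared
        epochs[t] = subj_gain[subj] * 20.0 * x  # ~20 uV scale

    return EpochSet(epochs=epochs, labels=labels, fs=spec.fs,
                    channel_names=list(spec.channel_names),
                    subject_ids=subjects)


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str, seed: int = 0,
                 effect_size: float = 1.0) -> tuple[EpochSet, dict]:
    """Build a named dataset plus a manifest of its assertable properties.

    * ``tiny``: 2 channels x 256 samples x 40 trials — unit tests.
    * ``default``: 5 channels x 1000 samples x 400 trials — integration runs.
    * ``paper_scale``: 5 channels x 10,000 samples x 40 trials — smoke tests
      at the reference architecture's input width.
    """
    if name == "tiny":
        spec = SimSpec(
            trials_per_class=20,
            channel_names=("Cz", "Pz"),
            epoch_len=256,
            fs=128.0,
            bands={"alpha": (10.0, 2.5), "beta": (20.0, 5.0)},
            band_amps={0: {"alpha": 1.2, "beta": 0.4},
                       1: {"alpha": 0.4, "beta": 1.1}},
            coupling={0: {("Cz", "Pz"): 0.7}, 1: {("Cz", "Pz"): 0.7}},
            n_subjects=4,
            effect_size=effect_size,
        )
    elif name == "default":
        spec = SimSpec(effect_size=effect_size)
    elif name == "paper_scale":
        spec = SimSpec(trials_per_class=20, epoch_len=10_000,
                       effect_size=effect_size)
    else:
        raise ValueError(f"unknown fixture {name!r}; "
                         "expected tiny / default / paper_scale")
    es = simulate_dataset(spec, seed)
    manifest = {
        "name": name,
        "seed": seed,
        "n_trials": es.n_trials,
        "n_channels": es.n_channels,
        "epoch_len": es.epoch_len,
        "fs": spec.fs,
        "effect_size": spec.effect_size,
        "class_balance": {0: spec.trials_per_class, 1: spec.trials_per_class},
        "planted_edges": sorted(tuple(sorted(p))
                                for p in spec.planted_edges()),
        "band_amps": spec.effective_band_amps(),
        "coupling": {cls: {"-".join(pair): c for pair, c in cmap.items()}
                     for cls, cmap in spec.effective_coupling().items()},
        "chance_accuracy": 0.5,
        "notes": (
            "AR(2) resonator band mixture + 1/f + white noise; class contrast "
            "in alpha/beta power and pair coupling; effect_size scales all "
            "class differences (0 = identical classes)."),
    }
    return es, manifest
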