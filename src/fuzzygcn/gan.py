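"""Per-class generative adversarial augmentation of EEG trials.

One GAN is trained per class. The generator maps a 100-dimensional uniform
latent vector through a widening dense stack (batch-normalized, Leaky-ReLU)
to a flattened single-vector trial in [0, 1]; the discriminator is a
narrowing five-layer dense stack ending in a sigmoid real/fake probability.
Training alternates discriminator and generator steps on the minimax value

    V(G, D) = E_x[log D(x)] + E_z[log(1 - D(G(z)))]

(the discriminator ascends V; the generator descends its fake term, with the
non-saturating -log D(G(z)) variant available). Multichannel trials are
handled channel-concatenated: a (C, T) trial becomes one length C*T vector.

Augmentation is strictly class-conditional and strictly train-partition-only:
generated trials carry provenance "gan" and the split guards refuse them
anywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .data import EpochSet, PROVENANCE_GAN
from .optim import SGD

_EPS = 1e-7  # clamp inside logs


@dataclass
class GANConfig:
    """Generator/discriminator architecture and training hyperparameters."""

    latent_dim: int = 100
    gen_widths: tuple[int, ...] = (512, 1024, 2048, 4096)
    out_len: int = 7500
    disc_widths: tuple[int, ...] | None = None  # default: derived, 5 layers
    lr: float = 1e-4
    iters: int = 200
    batch: int = 10
    leaky_slope: float = 0.2
    batchnorm: bool = True
    loss: str = "minimax"  # or "non_saturating"

    def __post_init__(self) -> None:
        widths = (*self.gen_widths, self.out_len)
        if any(b <= a for a, b in zip(widths, widths[1:])):
            raise ValueError("generator widths must increase strictly "
                             "up to out_len")
        if min(self.latent_dim, self.lr, self.iters, self.batch) <= 0:
            raise ValueError("all hyperparameters must be positive")
        if self.disc_widths is None:
            w = [max(self.out_len // (2 ** k), 4) for k in range(1, 5)]
            self.disc_widths = tuple(w)
        if self.loss not in ("minimax", "non_saturating"):
            raise ValueError(f"unknown GAN loss {self.loss!r}")

    @classmethod
    def desk(cls, out_len: int = 256, **overrides) -> "GANConfig":
        """Scaled-down widths preserving the reference x2 progression.

        Desk runs keep the 200-iteration budget but use SGD lr 0.1 and the
        non-saturating generator loss: at toy scale the reference lr 1e-4
        leaves both networks essentially at initialization after 200 steps.
        """
        widths = tuple(out_len // (2 ** k) for k in (4, 3, 2, 1))
        kwargs = dict(gen_widths=widths, out_len=out_len, lr=0.1,
                      loss="non_saturating")
        kwargs.update(overrides)
        return cls(**kwargs)


def gan_value(d_real: np.ndarray, d_fake: np.ndarray,
              loss: str = "minimax") -> tuple[float, float]:
    """(disc_loss, gen_loss) from discriminator probabilities.

    V = mean log d_real + mean log(1 - d_fake); the discriminator minimizes
    -V. The generator minimizes mean log(1 - d_fake) (minimax) or
    -mean log d_fake (non-saturating). Probabilities are eps-clamped.
    """
    dr = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1 - _EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1 - _EPS)
    v = float(np.mean(np.log(dr)) + np.mean(np.log(1.0 - df)))
    if loss == "minimax":
        gen_loss = float(np.mean(np.log(1.0 - df)))
    else:
        gen_loss = float(-np.mean(np.log(df)))
    return -v, gen_loss


class _MLP:
    """Sequential dense stack with shared layer plumbing."""

    def __init__(self, layers: list[nn.Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(l.params[k], l.grads[k])
                for l in self.layers for k in l.params]


class Generator:
    """Latent -> signal map; draws are deterministic given the passed RNG."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        layers: list[nn.Layer] = []
        widths = (cfg.latent_dim, *cfg.gen_widths, cfg.out_len)
        for i, (din, dout) in enumerate(zip(widths[:-1], widths[1:])):
            layers.append(nn.Dense(din, dout, rng))
            if i < len(widths) - 2:  # hidden layers
                if cfg.batchnorm:
                    layers.append(nn.BatchNorm(dout))
                layers.append(nn.ReLU(cfg.leaky_slope))
        layers.append(nn.Sigmoid())  # outputs live in [0, 1] like the data
        self.net = _MLP(layers)

    def sample_latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-1.0, 1.0, size=(n, self.cfg.latent_dim))

    def generate(self, n: int, rng: np.random.Generator,
                 training: bool = False) -> np.ndarray:
        """Draw n trials, shape (n, out_len)."""
        return self.net.forward(self.sample_latent(n, rng), training)


class Discriminator:
    def __init__(self, cfg: GANConfig, rng: np.random.Generator) -> None:
        layers: list[nn.Layer] = []
        widths = (cfg.out_len, *cfg.disc_widths, 1)
        for i, (din, dout) in enumerate(zip(widths[:-1], widths[1:])):
            layers.append(nn.Dense(din, dout, rng))
            if i < len(widths) - 2:
                layers.append(nn.ReLU(cfg.leaky_slope))
        layers.append(nn.Sigmoid())
        self.net = _MLP(layers)

    def prob(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(x, training)[:, 0]


def _as_matrix(es: EpochSet) -> np.ndarray:
    """Channel-concatenate trials and min-max scale each into [0, 1]."""
    flat = es.epochs.reshape(es.n_trials, -1)
    lo = flat.min(axis=1, keepdims=True)
    hi = flat.max(axis=1, keepdims=True)
    rng_ = np.where(hi > lo, hi - lo, 1.0)
    return (flat - lo) / rng_


def train_gan(real: EpochSet, cfg: GANConfig, seed: int
              ) -> tuple[Generator, Discriminator, dict]:
    """Adversarial training on one class's trials.

    Returns ``(generator, discriminator, log)``; the log carries the
    per-iteration value function and both losses. Deterministic under
    ``seed``.
    """
    x = _as_matrix(real)
    if x.shape[1] != cfg.out_len:
        raise ValueError(
            f"trials flatten to length {x.shape[1]} but cfg.out_len is "
            f"{cfg.out_len}")
    if x.shape[0] < cfg.batch:
        raise ValueError(f"need at least {cfg.batch} real trials, got "
                         f"{x.shape[0]}")
    rng = np.random.default_rng(seed)
    gen = Generator(cfg, rng)
    disc = Discriminator(cfg, rng)
    opt_g = SGD(lr=cfg.lr)
    opt_d = SGD(lr=cfg.lr)
    log = {"value": [], "disc_loss": [], "gen_loss": []}

    n = x.shape[0]
    for _ in range(cfg.iters):
        # --- discriminator step: ascend V
        idx = rng.choice(n, size=cfg.batch, replace=n < cfg.batch)
        xb = x[idx]
        fake = gen.generate(cfg.batch, rng, training=True)
        p_real = disc.prob(xb, training=True)
        d_real_grad = -1.0 / np.clip(p_real, _EPS, None) / cfg.batch
        disc.net.backward(d_real_grad[:, None])
        grads_real = [(p, g.copy()) for p, g in disc.net.pairs()]
        p_fake = disc.prob(fake, training=True)
        d_fake_grad = 1.0 / np.clip(1.0 - p_fake, _EPS, None) / cfg.batch
        disc.net.backward(d_fake_grad[:, None])
        # combine the two half-batches' gradients, then one SGD step
        combined = [(p, g + gr) for (p, g), (_, gr)
                    in zip(disc.net.pairs(), grads_real)]
        opt_d.step(combined)

        # --- generator step
        fake = gen.generate(cfg.batch, rng, training=True)
        p_fake = disc.prob(fake, training=True)
        if cfg.loss == "minimax":
            # minimize mean log(1 - D(G(z)))
            dout = -1.0 / np.clip(1.0 - p_fake, _EPS, None) / cfg.batch
        else:
            # non-saturating: minimize -mean log D(G(z))
            dout = -1.0 / np.clip(p_fake, _EPS, None) / cfg.batch
        dfake = disc.net.backward(dout[:, None])  # disc grads discarded
        gen.net.backward(dfake)
        opt_g.step(gen.net.pairs())

        disc_loss, gen_loss = gan_value(p_real, p_fake, cfg.loss)
        log["value"].append(-disc_loss)
        log["disc_loss"].append(disc_loss)
        log["gen_loss"].append(gen_loss)
    return gen, disc, log


def augment(es: EpochSet, target_per_class: int,
            generators: dict[int, Generator], seed: int = 0) -> EpochSet:
    """Append generated trials until each class reaches ``target_per_class``.

    Only ever apply this to the TRAINING partition; generated trials are
    flagged with provenance "gan" and the pipeline refuses them elsewhere.
    """
    rng = np.random.default_rng(seed)
    counts = es.class_counts()
    new_epochs, new_labels = [], []
    for cls, gen in sorted(generators.items()):
        have = counts.get(cls, 0)
        need = target_per_class - have
        if need <= 0:
            if target_per_class < have:
                warnings.warn(
                    f"class {cls} already has {have} >= {target_per_class} "
                    "trials; no augmentation", stacklevel=2)
            continue
        draws = gen.generate(need, rng)
        new_epochs.append(draws.reshape(need, es.n_channels, es.epoch_len))
        new_labels.append(np.full(need, cls, dtype=np.int64))
    if not new_epochs:
        return es.copy()
    n_new = sum(len(l) for l in new_labels)
    return EpochSet(
        epochs=np.concatenate([es.epochs, *new_epochs]),
        labels=np.concatenate([es.labels, *new_labels]),
        fs=es.fs,
        channel_names=list(es.channel_names),
        subject_ids=np.concatenate(
            [es.subject_ids, np.array(["gan"] * n_new, dtype=object)]),
        sources=np.concatenate(
            [es.sources, np.array([PROVENANCE_GAN] * n_new, dtype=object)]),
    )


# ---------------------------------------------------------------------------
# spectral sanity metric
# ---------------------------------------------------------------------------

def mean_power_spectrum(trials: np.ndarray) -> np.ndarray:
    """Mean normalized power spectrum over rows of a (n, T) matrix."""
    x = trials - trials.mean(axis=1, keepdims=True)
    p = np.abs(np.fft.rfft(x, axis=1)) ** 2
    p = p.mean(axis=0)
    total = p.sum()
    return p / total if total > 0 else p


def spectral_distance(a: np.ndarray, b: np.ndarray) -> float:
    """L2 distance between normalized mean power spectra."""
    return float(np.linalg.norm(a - b))
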