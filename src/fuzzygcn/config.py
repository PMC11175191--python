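"""YAML run-configuration loading.

A run config is a nested mapping with optional sections ``sim``, ``graph``,
``model``, ``tf2``, ``train`` and ``gan``; each section's keys map onto the
corresponding dataclass fields (``tf2.*`` keys fold into the model config).
Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

import yaml

from .gan import GANConfig
from .model import ModelConfig
from .simulate import SimSpec
from .training import SplitSpec, TrainConfig

_TF2_KEYS = {"alpha_init", "p_init", "n_init", "rho", "xi"}


def load_yaml(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return cfg


def _build(cls, section: dict, what: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {what} config keys: {sorted(unknown)}")
    return cls(**section)


def sim_spec(cfg: dict) -> SimSpec:
    sec = dict(cfg.get("sim", {}))
    if "channel_names" in sec:
        sec["channel_names"] = tuple(sec["channel_names"])
    return _build(SimSpec, sec, "sim")


def model_config(cfg: dict) -> ModelConfig:
    sec = dict(cfg.get("model", {}))
    for key, val in cfg.get("tf2", {}).items():
        if key not in _TF2_KEYS:
            raise ValueError(f"unknown tf2 config key: {key}")
        sec[f"tf2_{key}"] = val
    for key in ("dims", "cheb_orders"):
        if key in sec:
            sec[key] = tuple(sec[key])
    return _build(ModelConfig, sec, "model")


def train_config(cfg: dict) -> TrainConfig:
    return _build(TrainConfig, dict(cfg.get("train", {})), "train")


def split_spec(cfg: dict) -> SplitSpec:
    sec = dict(cfg.get("split", {}))
    if "fractions" in sec:
        sec["fractions"] = tuple(sec["fractions"])
    return _build(SplitSpec, sec, "split")


def gan_config(cfg: dict) -> GANConfig:
    sec = dict(cfg.get("gan", {}))
    for key in ("gen_widths", "disc_widths"):
        if key in sec and sec[key] is not None:
            sec[key] = tuple(sec[key])
    return _build(GANConfig, sec, "gan")


def graph_threshold(cfg: dict) -> float:
    return float(cfg.get("graph", {}).get("threshold", 0.3))
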