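"""Single-file HDF5 model checkpoints.

A checkpoint stores the layer weights (including batch-norm running stats and
the TF-2 triples), the serialized ModelConfig, and the channel graph's
adjacency + channel names, so a trained classifier can be rebuilt and applied
without access to the training data.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .graph import graph_from_adjacency
from .model import GCNModel, ModelConfig


def save_checkpoint(model: GCNModel, path: str,
                    extra: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("state")
        for k, v in model.state_arrays().items():
            grp.create_dataset(k, data=v)
        f.attrs["model_config"] = json.dumps(model.cfg.to_dict())
        f.create_dataset("adjacency", data=model.graph.W)
        f.attrs["channel_names"] = list(model.graph.channel_names)
        if extra:
            f.attrs["extra"] = json.dumps(extra)


def load_checkpoint(path: str) -> tuple[GCNModel, dict]:
    """Rebuild the model; returns (model, extra-metadata dict)."""
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["model_config"])
        for key in ("dims", "cheb_orders"):
            if cfg_dict.get(key) is not None:
                cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        graph = graph_from_adjacency(
            np.asarray(f["adjacency"]),
            [str(c) for c in f.attrs["channel_names"]])
        model = GCNModel(cfg, graph, seed=0)
        state = {k: np.asarray(v) for k, v in f["state"].items()}
        model.set_state(state)
        extra = json.loads(f.attrs["extra"]) if "extra" in f.attrs else {}
    return model, extra
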