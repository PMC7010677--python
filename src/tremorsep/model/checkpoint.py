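"""Self-describing HDF5 checkpoints: config, weights, history, seed.

Layout::

    /config          attrs: every NetworkConfig field
    /history/train_loss, /history/val_loss
    /layers/L{k}/{fwd,bwd}/{U_r,U_z,U,W_r,W_z,W,b_r,b_z,b_h}
    /head/{V_f,c_f,V_b,c_b}
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

from .gru import GRUCellParams, NetworkParams
from .network import NetworkConfig

__all__ = ["save_checkpoint", "load_checkpoint"]

_CELL_FIELDS = ("U_r", "U_z", "U", "W_r", "W_z", "W", "b_r", "b_z", "b_h")


def save_checkpoint(
    path, params: NetworkParams, config: NetworkConfig, history: dict | None = None
) -> None:
    with h5py.File(path, "w") as f:
        cfg = f.create_group("config")
        for fld in dataclasses.fields(config):
            cfg.attrs[fld.name] = getattr(config, fld.name)
        cfg.attrs["activation_used"] = params.activation
        hist = f.create_group("history")
        if history:
            for key, val in history.items():
                hist.create_dataset(key, data=np.asarray(val))
        layers = f.create_group("layers")
        for k, (fwd, bwd) in enumerate(params.layers):
            g = layers.create_group(f"L{k}")
            for name, cell in (("fwd", fwd), ("bwd", bwd)):
                cg = g.create_group(name)
                for fldname in _CELL_FIELDS:
                    cg.create_dataset(fldname, data=getattr(cell, fldname))
        head = f.create_group("head")
        for name in ("V_f", "c_f", "V_b", "c_b"):
            head.create_dataset(name, data=getattr(params, name))


def load_checkpoint(path) -> tuple[NetworkParams, NetworkConfig, dict]:
    with h5py.File(path, "r") as f:
        cfg_attrs = dict(f["config"].attrs)
        activation = str(cfg_attrs.pop("activation_used", "relu"))
        kwargs = {
            fld.name: cfg_attrs[fld.name]
            for fld in dataclasses.fields(NetworkConfig)
            if fld.name in cfg_attrs
        }
        for key in ("n_layers", "hidden_size", "window", "epochs", "batch_size", "seed"):
            if key in kwargs:
                kwargs[key] = int(kwargs[key])
        for key in ("rate_hz", "learning_rate"):
            if key in kwargs:
                kwargs[key] = float(kwargs[key])
        for key in ("activation", "dtype"):
            if key in kwargs:
                kwargs[key] = str(kwargs[key])
        config = NetworkConfig(**kwargs)
        history = {key: np.asarray(val) for key, val in f["history"].items()}
        layers = []
        for k in range(config.n_layers):
            g = f["layers"][f"L{k}"]
            cells = []
            for name in ("fwd", "bwd"):
                cells.append(
                    GRUCellParams(**{fld: g[name][fld][...] for fld in _CELL_FIELDS})
                )
            layers.append((cells[0], cells[1]))
        params = NetworkParams(
            layers=layers,
            V_f=f["head"]["V_f"][...],
            c_f=f["head"]["c_f"][...],
            V_b=f["head"]["V_b"][...],
            c_b=f["head"]["c_b"][...],
            activation=activation,
        )
    return params, config, history
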