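"""HDF5 checkpoints for networks and spike trains."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .lif import LayerParams
from .trainer import Network, NetworkSpec, RewireConfig

__all__ = ["save_checkpoint", "load_checkpoint", "save_spikes", "load_spikes"]

_LAYER_DATASETS = ("w_in", "w_rec", "bias", "tau", "mask_in", "mask_rec",
                   "coords")


def save_checkpoint(network: Network, path) -> None:
    """Write a network to an HDF5 container.

    One group per layer with named datasets (w_in, w_rec, bias, tau,
    mask_in, mask_rec, coords) and a JSON attribute block carrying u_th,
    the layer type and the full experiment spec.
    """
    with h5py.File(path, "w") as fh:
        fh.attrs["spec"] = json.dumps(asdict(network.spec))
        fh.create_dataset("input_coords", data=network.input_coords)
        for i, lp in enumerate(network.layers):
            grp = fh.create_group(f"layer_{i}")
            for name in _LAYER_DATASETS:
                grp.create_dataset(name, data=getattr(lp, name))
            grp.attrs["meta"] = json.dumps(
                {
                    "u_th": lp.u_th,
                    "kind": lp.kind,
                    "tau_shared": lp.tau_shared,
                }
            )


def load_checkpoint(path) -> Network:
    with h5py.File(path, "r") as fh:
        spec_dict = json.loads(fh.attrs["spec"])
        spec_dict["rewire"] = RewireConfig(**spec_dict["rewire"])
        spec_dict["layers"] = [tuple(l) for l in spec_dict["layers"]]
        spec = NetworkSpec(**spec_dict)
        input_coords = fh["input_coords"][()]
        layers = []
        for i in range(len(spec.layers)):
            grp = fh[f"layer_{i}"]
            meta = json.loads(grp.attrs["meta"])
            layers.append(
                LayerParams(
                    w_in=grp["w_in"][()],
                    w_rec=grp["w_rec"][()],
                    bias=grp["bias"][()],
                    tau=grp["tau"][()],
                    u_th=meta["u_th"],
                    mask_in=grp["mask_in"][()].astype(bool),
                    mask_rec=grp["mask_rec"][()].astype(bool),
                    coords=grp["coords"][()],
                    tau_shared=meta["tau_shared"],
                    kind=meta["kind"],
                )
            )
    return Network(layers=layers, input_coords=input_coords, spec=spec)


def save_spikes(spikes: np.ndarray, path, name: str = "spikes") -> None:
    """Store an encoded spike train (boolean) in HDF5."""
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        fh.create_dataset(name, data=np.asarray(spikes, dtype=bool))


def load_spikes(path, name: str = "spikes") -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh[name][()].astype(bool)
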