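"""HDF5 persistence for trial sets, spectral operators and model weights."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .model import CGCNN, ModelConfig
from .montage import SpectralOperators
from .representations import TrialSet

__all__ = ["save_trialset", "load_trialset", "save_operators",
           "save_weights", "load_weights"]


def save_trialset(path, trials: TrialSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("signals", data=trials.signals)
        fh.create_dataset("labels", data=trials.labels)
        fh.create_dataset("trial_ids", data=trials.trial_ids)
        fh.attrs["fs"] = float(trials.fs)
        if trials.electrode_names is not None:
            fh.attrs["electrode_names"] = json.dumps(list(trials.electrode_names))


def load_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as fh:
        names = fh.attrs.get("electrode_names")
        return TrialSet(
            signals=fh["signals"][...],
            labels=fh["labels"][...],
            trial_ids=fh["trial_ids"][...],
            fs=float(fh.attrs["fs"]),
            electrode_names=tuple(json.loads(names)) if names is not None else None,
        )


def save_operators(path_or_group, ops: SpectralOperators, adjacency=None) -> None:
    """Write degree/laplacian/cheb_basis (and optionally adjacency) datasets."""
    own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
    fh = h5py.File(path_or_group, "w") if own else path_or_group
    try:
        if adjacency is not None:
            fh.create_dataset("adjacency", data=np.asarray(adjacency))
        fh.create_dataset("degree", data=ops.degree)
        fh.create_dataset("laplacian", data=ops.laplacian_norm)
        fh.create_dataset("laplacian_scaled", data=ops.laplacian_scaled)
        fh.create_dataset("cheb_basis", data=ops.cheb_basis)
        fh.attrs["lambda_max"] = ops.lambda_max
        fh.attrs["cheb_order"] = ops.cheb_order
    finally:
        if own:
            fh.close()


def save_weights(path, model: CGCNN, adjacency: np.ndarray = None) -> None:
    """Weights + config + operators, enough to reload the model standalone."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("params")
        for name, value in model.params.items():
            grp.create_dataset(name, data=value)
        fh.attrs["config"] = json.dumps(model.config.to_dict())
        ops_grp = fh.create_group("operators")
        save_operators(ops_grp, model.ops,
                       adjacency=adjacency)


def load_weights(path) -> CGCNN:
    with h5py.File(path, "r") as fh:
        config = ModelConfig.from_dict(json.loads(fh.attrs["config"]))
        ops_grp = fh["operators"]
        ops = SpectralOperators(
            degree=ops_grp["degree"][...],
            laplacian_norm=ops_grp["laplacian"][...],
            lambda_max=float(ops_grp.attrs["lambda_max"]),
            laplacian_scaled=ops_grp["laplacian_scaled"][...],
            cheb_order=int(ops_grp.attrs["cheb_order"]),
            cheb_basis=ops_grp["cheb_basis"][...],
        )
        model = CGCNN(config, ops)
        for name in model.params:
            model.params[name] = fh["params"][name][...]
    return model
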