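"""HDF5 persistence for weight trajectories (datasets ``times`` and
``weights``, config and seed as attributes)."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from sleepsyn.binarynet import Model1Config, WeightTrajectory

__all__ = ["save_trajectory", "load_trajectory"]


def save_trajectory(traj: WeightTrajectory, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("weights", data=traj.weights, compression="gzip", compression_opts=4)
        if traj.config is not None:
            fh.attrs["config"] = json.dumps(dataclasses.asdict(traj.config))
        fh.attrs["seed"] = json.dumps(traj.seed, default=str)


def load_trajectory(path) -> WeightTrajectory:
    with h5py.File(path, "r") as fh:
        times = np.asarray(fh["times"])
        weights = np.asarray(fh["weights"])
        cfg = None
        if "config" in fh.attrs:
            cfg = Model1Config(**json.loads(fh.attrs["config"]))
        seed = json.loads(fh.attrs.get("seed", "null"))
    return WeightTrajectory(times=times, weights=weights, config=cfg, seed=seed)
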