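"""Trial-archive I/O.

The canonical on-disk layout is a single HDF5 file::

    /trials         float64, shape (I, n_channels, n_samples)
    /labels         int64, length I, -1 = unlabelled
    /fs             scalar
    /channel_names  variable-length strings (optional)

A plain-text alternative is also accepted: one CSV per trial (rows =
channels) plus a JSON sidecar carrying labels and the sampling rate.
"""

from __future__ import annotations

import json
import os
from glob import glob

import h5py
import numpy as np

__all__ = ["save_trials", "load_trials", "save_spd_set", "load_spd_set",
           "save_trials_csv", "load_trials_csv"]


def save_trials(
    path: str,
    X: np.ndarray,
    y: np.ndarray,
    fs: float,
    channel_names: list[str] | None = None,
) -> None:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 3 or X.shape[0] != y.shape[0]:
        raise ValueError("trials must be (I, n, Ts) with one label per trial")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("trials", data=X)
        fh.create_dataset("labels", data=y)
        fh.create_dataset("fs", data=float(fs))
        if channel_names is not None:
            fh.create_dataset(
                "channel_names",
                data=np.asarray(channel_names, dtype=h5py.string_dtype()),
            )


def load_trials(path: str) -> tuple[np.ndarray, np.ndarray, float, list[str] | None]:
    with h5py.File(path, "r") as fh:
        X = fh["trials"][()]
        y = fh["labels"][()]
        fs = float(fh["fs"][()])
        names = None
        if "channel_names" in fh:
            names = [s.decode() if isinstance(s, bytes) else str(s)
                     for s in fh["channel_names"][()]]
    return X, y, fs, names


def save_spd_set(path: str, matrices: np.ndarray) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrices", data=np.asarray(matrices, dtype=np.float64))


def load_spd_set(path: str) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh["matrices"][()]


def save_trials_csv(directory: str, X: np.ndarray, y: np.ndarray, fs: float) -> None:
    """One CSV per trial (rows = channels) plus a JSON sidecar."""
    os.makedirs(directory, exist_ok=True)
    X = np.asarray(X, dtype=float)
    for i, trial in enumerate(X):
        np.savetxt(os.path.join(directory, f"trial_{i:05d}.csv"), trial, delimiter=",")
    sidecar = {"fs": float(fs), "labels": [int(v) for v in np.asarray(y)]}
    with open(os.path.join(directory, "trials.json"), "w") as fh:
        json.dump(sidecar, fh)


def load_trials_csv(directory: str) -> tuple[np.ndarray, np.ndarray, float]:
    with open(os.path.join(directory, "trials.json")) as fh:
        sidecar = json.load(fh)
    files = sorted(glob(os.path.join(directory, "trial_*.csv")))
    X = np.stack([np.loadtxt(f, delimiter=",") for f in files])
    y = np.asarray(sidecar["labels"], dtype=np.int64)
    if len(files) != y.size:
        raise ValueError("sidecar labels do not match trial files")
    return X, y, float(sidecar["fs"])
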