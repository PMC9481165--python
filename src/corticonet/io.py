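"""File formats for connectomes and response tensors (HDF5 with CSV fallback)."""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .errors import InvalidInputError
from .flatmap import VoxelConnectome


def save_connectome(conn: VoxelConnectome, path: str | Path) -> None:
    """HDF5 layout: `positions` (N, 3), `labels` (N,), `weights` (N, N)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=conn.positions)
        f.create_dataset(
            "labels", data=np.asarray(conn.labels, dtype=h5py.string_dtype())
        )
        f.create_dataset("weights", data=conn.weights)


def load_connectome(path: str | Path) -> VoxelConnectome:
    with h5py.File(path, "r") as f:
        return VoxelConnectome(
            positions=f["positions"][...],
            labels=np.asarray([s.decode() for s in f["labels"][...]]),
            weights=f["weights"][...],
        )


def save_connectome_csv(conn: VoxelConnectome, prefix: str | Path) -> None:
    """CSV fallback: `<prefix>.voxels.csv` and sparse `<prefix>.weights.csv`."""
    prefix = Path(prefix)
    with open(f"{prefix}.voxels.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["x_um", "y_um", "z_um", "label"])
        for pos, lab in zip(conn.positions, conn.labels):
            w.writerow([f"{pos[0]:.6g}", f"{pos[1]:.6g}", f"{pos[2]:.6g}", lab])
    src, tgt = np.nonzero(conn.weights)
    with open(f"{prefix}.weights.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["source", "target", "weight"])
        for s, t in zip(src, tgt):
            w.writerow([s, t, f"{conn.weights[s, t]:.9g}"])


def load_connectome_csv(prefix: str | Path) -> VoxelConnectome:
    prefix = Path(prefix)
    positions, labels = [], []
    with open(f"{prefix}.voxels.csv", newline="") as f:
        for row in csv.DictReader(f):
            positions.append([float(row["x_um"]), float(row["y_um"]), float(row["z_um"])])
            labels.append(row["label"])
    n = len(positions)
    weights = np.zeros((n, n))
    with open(f"{prefix}.weights.csv", newline="") as f:
        for row in csv.DictReader(f):
            weights[int(row["source"]), int(row["target"])] = float(row["weight"])
    return VoxelConnectome(
        positions=np.asarray(positions), labels=np.asarray(labels), weights=weights
    )


def save_responses(
    T: np.ndarray,
    path: str | Path,
    image_ids: np.ndarray | None = None,
    neuron_ids: np.ndarray | None = None,
) -> None:
    """HDF5 layout: `responses` (images, neurons, trials) + id vectors."""
    T = np.asarray(T)
    if T.ndim != 3:
        raise InvalidInputError("response tensor must be 3-dimensional")
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=T)
        f.create_dataset(
            "image_ids",
            data=image_ids if image_ids is not None else np.arange(T.shape[0]),
        )
        f.create_dataset(
            "neuron_ids",
            data=neuron_ids if neuron_ids is not None else np.arange(T.shape[1]),
        )


def load_responses(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["responses"][...]
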