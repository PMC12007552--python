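"""Container file I/O.

One HDF5 file per run holds the data matrix, sensor geometry, masks and
labels; connectomes are written as plain-text CSV matrices plus a
long-format edge table. Round-trips are bit-exact for arrays and exact for
masks and labels.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .datatypes import Connectome, ParcelSet, Recording, SensorArray

__all__ = [
    "write_recording",
    "read_recording",
    "write_connectome",
    "read_connectome",
    "write_parcels",
    "read_parcels",
]

_REQUIRED = ("data", "positions", "orientations", "sensor_id")


class FormatError(ValueError):
    """Raised when a container file does not match the expected schema."""


def write_recording(path: str, rec: Recording, array: SensorArray) -> None:
    """Write a run (data + geometry + masks) to one HDF5 container."""
    if array.n_channels != rec.n_channels:
        raise ValueError("sensor array channel count does not match recording")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("positions", data=array.positions)
        f.create_dataset("orientations", data=array.orientations)
        f.create_dataset("sensor_id", data=array.sensor_id)
        f.create_dataset("channel_good", data=rec.channel_good)
        if rec.epoch_good is not None:
            f.create_dataset("epoch_good", data=rec.epoch_good)
        f.attrs["fs"] = rec.fs
        f.attrs["epoch_length_s"] = rec.epoch_length_s
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["run_id"] = rec.run_id


def read_recording(path: str) -> tuple[Recording, SensorArray]:
    """Read a run container; inverse of :func:`write_recording`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in _REQUIRED:
            if key not in f:
                raise FormatError(f"container {path!r} is missing field {key!r}")
        array = SensorArray(
            positions=f["positions"][()],
            orientations=f["orientations"][()],
            sensor_id=f["sensor_id"][()],
        )
        rec = Recording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_good=f["channel_good"][()] if "channel_good" in f else None,
            epoch_length_s=float(f.attrs.get("epoch_length_s", 5.0)),
            epoch_good=f["epoch_good"][()] if "epoch_good" in f else None,
            subject_id=str(f.attrs.get("subject_id", "s00")),
            run_id=str(f.attrs.get("run_id", "r1")),
        )
    return rec, array


def connectome_edge_table(conn: Connectome) -> pd.DataFrame:
    """Long-format unordered-pair edge list (region_i < region_j)."""
    m = conn.values
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return pd.DataFrame(
        {"region_i": iu, "region_j": ju, "value": m[iu, ju]}
    )


def write_connectome(conn: Connectome, path: str) -> None:
    """Write a connectome as a CSV matrix plus a ``*_edges.csv`` table.

    The edge table has one row per unordered region pair (i < j); a
    78-parcel connectome therefore yields 3003 rows.
    """
    m = conn.values
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("connectome matrix must be symmetric")
    pd.DataFrame(m).to_csv(path, index=False, header=False)
    base, ext = os.path.splitext(path)
    edges = connectome_edge_table(conn)
    edges.to_csv(f"{base}_edges{ext or '.csv'}", index=False)


def read_connectome(path: str, band: str = "unknown", **meta) -> Connectome:
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return Connectome(values=values, band=band, **meta)


def write_parcels(path: str, parcels: ParcelSet) -> None:
    df = pd.DataFrame(parcels.centroids, columns=["x", "y", "z"])
    df.insert(0, "label", list(parcels.labels))
    df.to_csv(path, index=False)


def read_parcels(path: str) -> ParcelSet:
    df = pd.read_csv(path)
    return ParcelSet(
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
        labels=df["label"].tolist(),
    )
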