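"""On-disk layouts: HDF5 for recordings and epochs, TSV/CSV for tables.

Recording layout (HDF5): ``/data`` (n_channels × n_samples float64, μV),
attrs ``channels`` (list of str), ``sfreq``, ``subject``; ``/events`` as
one column dataset per field.  EpochSet adds ``/epochs`` (n_epochs ×
n_channels × n_times), ``/times``, ``/kept``, ``/reject_reason`` and the
metadata columns.  Feature tables travel as tidy CSV; event logs and
rejection logs as TSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from attnloc.synthdata import Recording
from attnloc.preprocess import EpochSet


def _write_df(group: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        values = df[col].to_numpy()
        if values.dtype == object or values.dtype.kind in "US":
            values = values.astype("S")
        group.create_dataset(col, data=values)
    group.attrs["columns"] = list(df.columns)


def _read_df(group: h5py.Group) -> pd.DataFrame:
    cols = list(group.attrs["columns"])
    data = {}
    for col in cols:
        values = group[col][()]
        if values.dtype.kind == "S":
            values = values.astype(str)
        data[col] = values
    return pd.DataFrame(data)


def save_recording(recording: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["channels"] = list(recording.channels)
        f.attrs["sfreq"] = recording.sfreq
        f.attrs["subject"] = recording.subject
        _write_df(f.create_group("events"), recording.events)


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][()],
            channels=tuple(f.attrs["channels"]),
            sfreq=float(f.attrs["sfreq"]),
            events=_read_df(f["events"]),
            subject=str(f.attrs["subject"]),
        )


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("kept", data=epochs.kept)
        f.create_dataset("reject_reason",
                         data=epochs.reject_reason.astype("S"))
        f.attrs["channels"] = list(epochs.channels)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["subject"] = epochs.subject
        _write_df(f.create_group("metadata"), epochs.metadata)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["epochs"][()],
            channels=tuple(f.attrs["channels"]),
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            metadata=_read_df(f["metadata"]),
            kept=f["kept"][()].astype(bool),
            reject_reason=f["reject_reason"][()].astype(str).astype(object),
            subject=str(f.attrs["subject"]),
        )


def save_event_log(recording: Recording, path: str | Path) -> None:
    recording.events.to_csv(path, sep="\t", index=False)


def save_rejection_log(epochs: EpochSet, path: str | Path) -> None:
    epochs.rejection_log().to_csv(path, sep="\t", index=False)


def save_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def load_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
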