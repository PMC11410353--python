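"""Container I/O: HDF5 epochs files, CSV ERP exports, YAML configs.

The epochs container stores ``/data`` (trials x channels x samples, uV),
``/times`` (ms), one dataset per metadata column under ``/metadata``, the
layout as embedded JSON, and the provenance history as JSON attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .layout import ChannelLayout
from .synthetic_eeg import EpochArray
from .immn import ERPWaveform, DifferenceWave

__all__ = [
    "save_epochs",
    "load_epochs",
    "erp_to_csv",
    "erp_from_csv",
    "load_config",
    "save_difference_waves",
    "load_difference_waves",
]


def save_epochs(epochs: EpochArray, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        grp = f.create_group("metadata")
        for col in epochs.metadata.columns:
            values = epochs.metadata[col].to_numpy()
            if values.dtype == object or values.dtype.kind in "US":
                values = np.array([str(v) for v in values], dtype="S")
            grp.create_dataset(col, data=values)
        grp.attrs["columns"] = json.dumps(list(epochs.metadata.columns))
        f.attrs["layout"] = epochs.layout.to_json()
        f.attrs["history"] = json.dumps(epochs.history)


def load_epochs(path) -> EpochArray:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        cols = json.loads(f["metadata"].attrs["columns"])
        md = {}
        for col in cols:
            values = f["metadata"][col][()]
            if values.dtype.kind == "S":
                values = np.array([v.decode() for v in values])
            md[col] = values
        layout = ChannelLayout.from_json(f.attrs["layout"])
        history = json.loads(f.attrs["history"])
    metadata = pd.DataFrame(md)
    for col in ("analyzable", "artifact"):
        if col in metadata.columns:
            metadata[col] = metadata[col].astype(bool)
    return EpochArray(data=data, times=times, metadata=metadata,
                      layout=layout, history=history)


def erp_to_csv(wave: ERPWaveform | DifferenceWave, path, channel_names: list[str]) -> None:
    """Rows = time (ms), columns = channels."""
    df = pd.DataFrame(wave.data.T, columns=channel_names)
    df.insert(0, "time_ms", wave.times)
    df.to_csv(path, index=False)


def erp_from_csv(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path)
    times = df.pop("time_ms").to_numpy()
    return df.to_numpy().T, times, list(df.columns)


def save_difference_waves(waves: list[DifferenceWave], path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["times"] = waves[0].times
        for i, w in enumerate(waves):
            g = f.create_group(f"wave{i:04d}")
            g.create_dataset("data", data=w.data)
            g.attrs.update({
                "participant": w.participant, "contrast": w.contrast,
                "deviant_condition": w.deviant_condition,
                "n_deviant_trials": w.n_deviant_trials,
                "n_standard_trials": w.n_standard_trials,
            })


def load_difference_waves(path) -> list[DifferenceWave]:
    waves = []
    with h5py.File(path, "r") as f:
        times = f.attrs["times"][()]
        for key in sorted(f.keys()):
            g = f[key]
            waves.append(DifferenceWave(
                participant=g.attrs["participant"],
                contrast=g.attrs["contrast"],
                deviant_condition=g.attrs["deviant_condition"],
                data=g["data"][()],
                times=np.asarray(times, float),
                n_deviant_trials=int(g.attrs["n_deviant_trials"]),
                n_standard_trials=int(g.attrs["n_standard_trials"]),
            ))
    return waves


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
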