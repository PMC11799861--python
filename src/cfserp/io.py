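"""On-disk containers: HDF5 arrays with JSON sidecar metadata, TSV tables."""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import pandas as pd

from . import __version__
from .preproc import ConditionMeans
from .synth import EpochSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_condition_means",
    "load_condition_means",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _table_to_str(df: pd.DataFrame) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def _table_from_str(s: str) -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(s), sep="\t")


def save_epochs(epochs: EpochSet, path, seed: int | None = None) -> Path:
    """Write an EpochSet to chunked HDF5 plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "data",
            data=epochs.data,
            chunks=(1, min(64, epochs.n_trials), epochs.n_channels, epochs.data.shape[3]),
            compression="gzip",
            compression_opts=1,
        )
        f.create_dataset("times", data=epochs.times)
        f.attrs["labels_tsv"] = _table_to_str(epochs.labels)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["channel_names"] = json.dumps(epochs.channel_names)
        f.attrs["baseline_window"] = list(epochs.baseline_window)
    meta = {
        "kind": "EpochSet",
        "shape": list(epochs.data.shape),
        "dims": ["subject", "trial", "channel", "time"],
        "units": "uV",
        "sampling_rate": epochs.sampling_rate,
        "times_ms": [float(epochs.times[0]), float(epochs.times[-1])],
        "channel_names": epochs.channel_names,
        "seed": seed,
        "generator_version": __version__,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_epochs(path) -> EpochSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            labels=_table_from_str(f.attrs["labels_tsv"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_names=json.loads(f.attrs["channel_names"]),
            baseline_window=tuple(f.attrs["baseline_window"]),
        )


def save_condition_means(cm: ConditionMeans, path) -> Path:
    """Write ConditionMeans to HDF5 with a condition-axis JSON descriptor."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cm.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=cm.times)
        if cm.n_trials_per_cell is not None:
            f.create_dataset("n_trials_per_cell", data=cm.n_trials_per_cell)
        f.attrs["cells"] = json.dumps([list(c) for c in cm.cells])
        f.attrs["sampling_rate"] = cm.sampling_rate
        f.attrs["channel_names"] = json.dumps(cm.channel_names)
    meta = {
        "kind": "ConditionMeans",
        "shape": list(cm.data.shape),
        "dims": ["subject", "condition", "channel", "time"],
        "condition_axis": [
            {"expression": e, "contrast_level": l, "cfs": bool(v)}
            for e, l, v in cm.cells
        ],
        "sampling_rate": cm.sampling_rate,
        "generator_version": __version__,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_condition_means(path) -> ConditionMeans:
    path = Path(path)
    with h5py.File(path, "r") as f:
        counts = (
            f["n_trials_per_cell"][()] if "n_trials_per_cell" in f else None
        )
        return ConditionMeans(
            data=f["data"][()],
            cells=[(e, l, bool(v)) for e, l, v in json.loads(f.attrs["cells"])],
            times=f["times"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_names=json.loads(f.attrs["channel_names"]),
            n_trials_per_cell=counts,
        )
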