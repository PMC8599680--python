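"""File formats: TSV+JSON for raw recordings, HDF5 for epochs and evoked
traces, YAML for configurations.

Raw recordings travel as human-readable TSV (columns ``time_s``, ``trigger``,
then one ``<site>_<axis>`` column per channel, field values in fT) with a
JSON sidecar carrying the acquisition metadata. Multi-trial arrays use HDF5.
All on-disk times are seconds (raw) or milliseconds post-stimulus (epoched);
all fields are fT.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocessing import EpochSet, EvokedResponse
from .synthetic import RawRecording, SyntheticConfig

__all__ = [
    "write_raw", "read_raw",
    "write_epochs", "read_epochs",
    "write_evoked", "read_evoked",
    "write_config", "read_config",
    "sidecar_path",
]


def sidecar_path(tsv_path: str | Path) -> Path:
    return Path(tsv_path).with_suffix(".json")


def write_raw(raw: RawRecording, tsv_path: str | Path,
              metadata: dict | None = None) -> Path:
    """Write a recording as TSV plus a JSON metadata sidecar.

    Floats are written at full precision so the round trip is lossless.
    Returns the sidecar path.
    """
    tsv_path = Path(tsv_path)
    header = "\t".join(["time_s", "trigger", *raw.channel_labels])
    data = np.column_stack([raw.time, raw.trigger.astype(float), raw.channels])
    fmt = ["%.17g", "%d"] + ["%.17g"] * len(raw.channel_labels)
    np.savetxt(tsv_path, data, fmt=fmt, delimiter="\t",
               header=header, comments="")
    meta = {
        "sampling_rate": raw.sampling_rate,
        "channel_labels": list(raw.channel_labels),
        "units": {"time": "s", "field": "fT"},
    }
    if metadata:
        meta.update(metadata)
    side = sidecar_path(tsv_path)
    side.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return side


def read_raw(tsv_path: str | Path) -> RawRecording:
    """Read a TSV recording; sampling rate comes from the sidecar if present,
    otherwise from the time column spacing."""
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    for col in ("time_s", "trigger"):
        if col not in df.columns:
            raise ValueError(
                f"{tsv_path.name}: missing required column {col!r} "
                f"(found {list(df.columns)})")
    labels = [c for c in df.columns if c not in ("time_s", "trigger")]
    if not labels:
        raise ValueError(f"{tsv_path.name}: no data channels")
    side = sidecar_path(tsv_path)
    if side.exists():
        meta = json.loads(side.read_text())
        fs = float(meta["sampling_rate"])
        if meta.get("channel_labels") and list(meta["channel_labels"]) != labels:
            raise ValueError(
                f"{tsv_path.name}: sidecar channel labels disagree with header")
    else:
        fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    return RawRecording(
        time=df["time_s"].to_numpy(dtype=float),
        channels=df[labels].to_numpy(dtype=float),
        channel_labels=labels,
        trigger=df["trigger"].to_numpy(dtype=np.int64),
        sampling_rate=fs,
    )


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=epochs.trials)
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.attrs["channel_labels"] = json.dumps(epochs.channel_labels)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["kept"] = json.dumps(epochs.kept)
        f.attrs["rejected"] = json.dumps(epochs.rejected)
        f.attrs["units"] = "fT / ms"


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            trials=f["trials"][()],
            time_ms=f["time_ms"][()],
            channel_labels=json.loads(f.attrs["channel_labels"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            kept=json.loads(f.attrs["kept"]),
            rejected=json.loads(f.attrs["rejected"]),
        )


def write_evoked(evoked: EvokedResponse, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=evoked.time_ms)
        f.create_dataset("mean", data=evoked.mean)
        f.create_dataset("sem", data=evoked.sem)
        f.attrs["channel"] = evoked.channel
        f.attrs["n_trials"] = evoked.n_trials
        f.attrs["units"] = "fT / ms"


def read_evoked(path: str | Path) -> EvokedResponse:
    with h5py.File(path, "r") as f:
        return EvokedResponse(
            time_ms=f["time_ms"][()],
            mean=f["mean"][()],
            sem=f["sem"][()],
            n_trials=int(f.attrs["n_trials"]),
            channel=str(f.attrs["channel"]),
        )


def write_config(config, path: str | Path) -> None:
    """Serialize any config object exposing ``to_dict`` to YAML."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_config(path: str | Path, cls=SyntheticConfig):
    """Load a YAML config into ``cls`` via its ``from_dict``."""
    return cls.from_dict(yaml.safe_load(Path(path).read_text()))
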