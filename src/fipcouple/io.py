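"""Session, event and ground-truth I/O.

Sessions are stored either as delimited tables (columns ``time_s`` plus one
column per channel: ``region_a_raw``, ``region_b_raw``, ``isosbestic_a``,
``isosbestic_b``) or as HDF5 groups (datasets ``time`` and ``channels/<name>``,
attribute ``sampling_rate``). Events are delimited tables with columns
``event_type, onset_s, offset_s, attributes`` (attributes JSON-encoded);
lick/cue streams are one timestamp per line; ground truth is a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import BehaviorEvent
from .preprocess import PhotometrySession
from .synthetic import GroundTruth

__all__ = [
    "write_session_csv", "read_session_csv",
    "write_session_hdf5", "read_session_hdf5",
    "write_events_csv", "read_events_csv",
    "write_timestamps", "read_timestamps",
    "write_ground_truth", "read_ground_truth",
]


def write_session_csv(session: PhotometrySession, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": session.time})
    for name, trace in session.channels.items():
        df[name] = trace
    df.to_csv(path, index=False)


def read_session_csv(
    path: str | Path, sampling_rate: float | None = None
) -> PhotometrySession:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("session table lacks required column 'time_s'")
    time = df["time_s"].to_numpy()
    channels = {c: df[c].to_numpy() for c in df.columns if c != "time_s"}
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return PhotometrySession(time=time, channels=channels, sampling_rate=sampling_rate)


def write_session_hdf5(session: PhotometrySession, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=session.time)
        grp = f.create_group("channels")
        for name, trace in session.channels.items():
            grp.create_dataset(name, data=trace)
        f.attrs["sampling_rate"] = session.sampling_rate
        f.attrs["metadata"] = json.dumps(session.metadata, default=str)


def read_session_hdf5(path: str | Path) -> PhotometrySession:
    with h5py.File(path, "r") as f:
        time = f["time"][:]
        channels = {name: ds[:] for name, ds in f["channels"].items()}
        fs = float(f.attrs["sampling_rate"])
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    return PhotometrySession(time=time, channels=channels, sampling_rate=fs,
                             metadata=metadata)


def write_events_csv(events: list[BehaviorEvent], path: str | Path) -> None:
    rows = [
        {
            "event_type": e.event_type,
            "onset_s": e.onset,
            "offset_s": e.offset,
            "attributes": json.dumps(e.attributes),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["event_type", "onset_s", "offset_s", "attributes"]
                 ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[BehaviorEvent]:
    df = pd.read_csv(path)
    required = {"event_type", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table lacks required columns: {sorted(missing)}")
    events = []
    for _, row in df.iterrows():
        attrs = {}
        if "attributes" in df.columns and isinstance(row["attributes"], str):
            attrs = json.loads(row["attributes"])
        events.append(BehaviorEvent(row["event_type"], float(row["onset_s"]),
                                    float(row["offset_s"]), attrs))
    return events


def write_timestamps(times, path: str | Path) -> None:
    Path(path).write_text("\n".join(f"{t:.6f}" for t in np.asarray(times)) + "\n")


def read_timestamps(path: str | Path) -> np.ndarray:
    text = Path(path).read_text().split()
    return np.asarray([float(t) for t in text])


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    d = dataclasses.asdict(truth)
    d.pop("latent_drive", None)  # array; not serialized in the sidecar
    d["event_onsets"] = np.asarray(d["event_onsets"]).tolist()
    d["true_plateau"] = list(d["true_plateau"])
    Path(path).write_text(json.dumps(d, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        true_lag=d["true_lag"],
        true_correlation=d["true_correlation"],
        true_beta=d["true_beta"],
        event_onsets=np.asarray(d["event_onsets"]),
        true_plateau=tuple(d["true_plateau"]),
    )
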