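"""Readers and writers for recordings, behavior tables and pipeline artifacts.

Recordings travel either as delimited text (one column per channel) with a
JSON sidecar carrying the sampling rate and time origin, or as HDF5
datasets.  Percept timelines are two-column event tables (time_s, percept)
plus the scalar metadata needed to rebuild them.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import KoopstreamError, PerceptTimeline, Recording

__all__ = ["save_recording_text", "load_recording_text",
           "save_recording_h5", "load_recording_h5",
           "save_timeline", "load_timeline"]


def save_recording_text(rec: Recording, path) -> None:
    path = Path(path)
    header = "\t".join(f"ch{c}" for c in range(rec.n_channels))
    np.savetxt(path, rec.values, delimiter="\t", header=header, comments="")
    sidecar = {"rate": rec.rate, "t0": rec.t0}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_recording_text(path) -> Recording:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise KoopstreamError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    values = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return Recording(values=values, rate=meta["rate"], t0=meta.get("t0", 0.0))


def save_recording_h5(rec: Recording, path, dataset: str = "lfp") -> None:
    with h5py.File(path, "a") as f:
        if dataset in f:
            del f[dataset]
        d = f.create_dataset(dataset, data=rec.values)
        d.attrs["rate"] = rec.rate
        d.attrs["t0"] = rec.t0


def load_recording_h5(path, dataset: str = "lfp") -> Recording:
    with h5py.File(path, "r") as f:
        d = f[dataset]
        return Recording(values=d[...], rate=float(d.attrs["rate"]),
                         t0=float(d.attrs.get("t0", 0.0)))


def save_timeline(timeline: PerceptTimeline, path) -> None:
    """Event table: one row per epoch onset (time_s, percept), plus presses
    and scalar metadata in a JSON sidecar."""
    path = Path(path)
    onsets = np.concatenate([[0.0], timeline.switch_times])
    pd.DataFrame({"time_s": onsets,
                  "percept": timeline.percept_sequence}).to_csv(
        path, sep="\t", index=False)
    meta = {"reaction_time": timeline.reaction_time,
            "block_duration": timeline.block_duration,
            "triplet_duration": timeline.triplet_duration,
            "button_times": timeline.button_times.tolist()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_timeline(path) -> PerceptTimeline:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PerceptTimeline(
        switch_times=table["time_s"].to_numpy()[1:],
        percept_sequence=list(table["percept"]),
        reaction_time=meta["reaction_time"],
        block_duration=meta["block_duration"],
        triplet_duration=meta.get("triplet_duration", 0.6))
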