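"""Readers and writers for the on-disk containers.

Recordings travel as HDF5: a ``/data`` dataset (channels x samples,
float64, microvolts) with ``sample_rate`` and ``channel_ids`` attributes,
plus a ``/layout`` group carrying ``angles_deg``, ``midline_index``,
``device_length_mm`` and ``coverage_fraction``.  Event tables are plain
CSV with the header ``time_s,label,stim_amplitude_uA``.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from .types import (
    ElectrodeLayout,
    EventTable,
    FormatError,
    Recording,
)

_EVENT_COLUMNS = ["time_s", "label", "stim_amplitude_uA"]


def write_recording(recording: Recording, path: str | os.PathLike) -> None:
    """Write a Recording to an HDF5 container, overwriting any existing file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["sample_rate"] = float(recording.sample_rate)
        f.attrs["channel_ids"] = [str(c) for c in recording.channel_ids]
        if recording.annotations:
            f.attrs["annotations"] = json.dumps(recording.annotations)
        if recording.layout is not None:
            g = f.create_group("layout")
            g.create_dataset("angles_deg", data=recording.layout.angles_deg)
            g.attrs["midline_index"] = int(recording.layout.midline_index)
            g.attrs["device_length_mm"] = float(recording.layout.device_length_mm)
            g.attrs["coverage_fraction"] = float(recording.layout.coverage_fraction)


def read_recording(path: str | os.PathLike) -> Recording:
    """Read a Recording written by :func:`write_recording`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FormatError
        If the container lacks required datasets or attributes.
    LayoutMismatchError
        If the stored layout's electrode count differs from the channel count.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such recording file: {path}")
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError(f"{path}: missing /data dataset")
        if "sample_rate" not in f.attrs:
            raise FormatError(f"{path}: missing required attribute 'sample_rate'")
        data = np.asarray(f["data"], dtype=float)
        sample_rate = float(f.attrs["sample_rate"])
        channel_ids = None
        if "channel_ids" in f.attrs:
            channel_ids = [
                c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs["channel_ids"]
            ]
        annotations = {}
        if "annotations" in f.attrs:
            annotations = json.loads(f.attrs["annotations"])
        layout = None
        if "layout" in f:
            g = f["layout"]
            try:
                layout = ElectrodeLayout(
                    angles_deg=np.asarray(g["angles_deg"], dtype=float),
                    midline_index=int(g.attrs["midline_index"]),
                    device_length_mm=float(g.attrs["device_length_mm"]),
                    coverage_fraction=float(g.attrs["coverage_fraction"]),
                )
            except KeyError as exc:
                raise FormatError(f"{path}: incomplete /layout group ({exc})") from exc
    return Recording(
        data=data,
        sample_rate=sample_rate,
        channel_ids=channel_ids,
        layout=layout,
        annotations=annotations,
    )


def write_events(table: EventTable, path: str | os.PathLike) -> None:
    """Write an EventTable as CSV with header time_s,label,stim_amplitude_uA."""
    df = pd.DataFrame(
        {
            "time_s": table.time_s,
            "label": table.label,
            "stim_amplitude_uA": table.stim_amplitude_uA,
        }
    )
    df.to_csv(path, index=False)


def read_events(path: str | os.PathLike) -> EventTable:
    """Read an EventTable CSV; label and monotonicity checks apply."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such event file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return EventTable(
        time_s=df["time_s"].to_numpy(dtype=float),
        label=[str(v) for v in df["label"]],
        stim_amplitude_uA=df["stim_amplitude_uA"].to_numpy(dtype=float),
    )
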