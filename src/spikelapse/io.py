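"""File formats: LFP binary + JSON sidecar, and the pipeline's CSV tables.

LFP traces are stored as little-endian float32 samples with a JSON
sidecar ``<stem>.json`` holding ``{"fs_hz": ..., "units": "uV"}``.
Tabular artifacts (trajectories, trials, events, windows, zone tables,
posterior draws) are plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .is_detection import EventSeries, LabeledWindow, LfpTrace
from .maze_zones import Trajectory

__all__ = [
    "write_lfp",
    "read_lfp",
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "read_events",
    "write_windows",
    "read_windows",
]


def write_lfp(trace: LfpTrace, path: str | Path) -> None:
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    sidecar = {"fs_hz": trace.fs_hz, "units": "uV", "n_samples": len(trace.samples)}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_lfp(path: str | Path) -> LfpTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    samples = np.fromfile(path, dtype="<f4").astype(float)
    return LfpTrace(samples=samples, fs_hz=float(meta["fs_hz"]))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(t_s=df["t_s"].to_numpy(), x_cm=df["x_cm"].to_numpy(),
                      y_cm=df["y_cm"].to_numpy())


def write_events(events: EventSeries, path: str | Path) -> None:
    df = pd.DataFrame({
        "t_s": events.times_s,
        "label": events.labels,
        "bird_id": events.bird_id,
    })
    if events.amplitude_rms is not None:
        df["amplitude_rms"] = events.amplitude_rms
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> EventSeries:
    df = pd.read_csv(path)
    return EventSeries(
        times_s=df["t_s"].to_numpy(),
        labels=df["label"].to_numpy(dtype=object),
        bird_id=df["bird_id"].to_numpy(),
        amplitude_rms=df["amplitude_rms"].to_numpy() if "amplitude_rms" in df else None,
    )


def write_windows(windows: list[LabeledWindow], path: str | Path) -> None:
    pd.DataFrame({
        "t_start_s": [w.t_start_s for w in windows],
        "t_end_s": [w.t_end_s for w in windows],
        "contains_event": [w.contains_event for w in windows],
    }).to_csv(path, index=False)


def read_windows(path: str | Path) -> list[LabeledWindow]:
    df = pd.read_csv(path)
    return [
        LabeledWindow(t_start_s=r.t_start_s, t_end_s=r.t_end_s,
                      contains_event=bool(r.contains_event))
        for r in df.itertuples()
    ]
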