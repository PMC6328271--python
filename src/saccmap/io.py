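"""Plain-text readers and writers.

Gaze traces are tab-separated sample files (time_ms, x_dva, y_dva, valid);
trial logs are CSV with a versioned comment header; run manifests are JSON.
An adapter for real tracker exports only needs to produce these two text
formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze import GazeTrace
from .records import TRIAL_LOG_VERSION, frame_to_trials, trials_to_frame


def write_gaze_tsv(path, trace: GazeTrace) -> None:
    arr = np.column_stack([trace.t, trace.x, trace.y, trace.valid.astype(int)])
    np.savetxt(path, arr, delimiter="\t", fmt=("%.1f", "%.5f", "%.5f", "%d"),
               header="time_ms\tx_dva\ty_dva\tvalid", comments="")


def read_gaze_tsv(path) -> GazeTrace:
    df = pd.read_csv(path, sep="\t")
    x = df["x_dva"].to_numpy()
    y = df["y_dva"].to_numpy()
    valid = df["valid"].to_numpy().astype(bool)
    return GazeTrace(t=df["time_ms"].to_numpy(), x=x, y=y, valid=valid)


def write_trial_log(path, trials) -> None:
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    with open(path, "w") as fh:
        fh.write(f"# {TRIAL_LOG_VERSION}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_trial_log(path, as_records: bool = False):
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(f"# {TRIAL_LOG_VERSION}"):
            raise ValueError(f"unrecognized trial-log header: {first!r}")
        df = pd.read_csv(fh)
    return frame_to_trials(df) if as_records else df


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_jsonable) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value"):
        return obj.value
    return str(obj)
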