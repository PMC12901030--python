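"""On-disk formats: epoch arrays with JSON sidecars, gaze/event tables.

Epoch sets are stored as one binary array file per session
(``<name>.npy``) plus a JSON sidecar (``<name>.json``) holding the
sampling rate, time origin, channel names and per-trial metadata
records.  Gaze records are delimited text with columns (trial, t, x, y,
pupil); event and saccade tables are tab-separated text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, GazeRecord


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (tuple, list, np.ndarray)):
        return [_jsonable(x) for x in v]
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def save_epochs(path: str | Path, epochs: EpochSet, name: str = "epochs") -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / f"{name}.npy", epochs.data)
    records = [
        {k: _jsonable(v) for k, v in row.items()}
        for row in epochs.meta.to_dict(orient="records")
    ]
    sidecar = dict(fs=epochs.fs, t0=epochs.t0,
                   channel_names=epochs.channel_names, trials=records)
    (path / f"{name}.json").write_text(json.dumps(sidecar))


def load_epochs(path: str | Path, name: str = "epochs") -> EpochSet:
    path = Path(path)
    data = np.load(path / f"{name}.npy")
    sidecar = json.loads((path / f"{name}.json").read_text())
    meta = pd.DataFrame(sidecar["trials"])
    for col in ("contrasts", "orientations"):
        if col in meta:
            meta[col] = meta[col].apply(tuple)
    return EpochSet(data=data, fs=sidecar["fs"], t0=sidecar["t0"],
                    meta=meta, channel_names=sidecar.get("channel_names"))


def save_gaze(path: str | Path, gaze: GazeRecord) -> None:
    """Write gaze as delimited text (trial, t, x, y, pupil) plus the
    planted ground truth as a sidecar table."""
    path = Path(path)
    t = gaze.times
    frames = []
    for i in range(gaze.n_trials):
        frames.append(pd.DataFrame(dict(
            trial=i, t=t, x=gaze.x[i], y=gaze.y[i], pupil=gaze.pupil[i])))
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6g")
    planted = [
        dict(trial=i, onset=float(on))
        for i, arr in enumerate(gaze.planted_saccade_times) for on in arr
    ]
    pd.DataFrame(planted, columns=["trial", "onset"]).to_csv(
        Path(str(path) + ".truth.tsv"), sep="\t", index=False)


def load_gaze(path: str | Path, fs: float | None = None) -> GazeRecord:
    df = pd.read_csv(path, sep="\t")
    trials = sorted(df["trial"].unique())
    x, y, pupil = [], [], []
    t = None
    for tr in trials:
        g = df[df["trial"] == tr].sort_values("t")
        x.append(g["x"].to_numpy())
        y.append(g["y"].to_numpy())
        pupil.append(g["pupil"].to_numpy())
        t = g["t"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    rec = GazeRecord(x=np.asarray(x), y=np.asarray(y),
                     pupil=np.asarray(pupil), fs=fs, t0=float(t[0]))
    truth = Path(str(path) + ".truth.tsv")
    if truth.exists():
        tv = pd.read_csv(truth, sep="\t")
        rec.planted_saccade_times = [
            tv.loc[tv["trial"] == tr, "onset"].to_numpy() for tr in trials
        ]
    return rec


def save_events(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
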