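"""Containers and on-disk formats.

Trial tables travel as long-format CSV (one row per cue).  Continuous
recordings are stored as a raw little-endian float32 binary (channels x
samples, C order) next to a JSON sidecar holding the sampling rate, channel
names and the event-marker table (0-based sample indices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .task import TrialRecord, _INT_TO_CUE, cue_to_int

__all__ = [
    "ContinuousRecording",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
    "save_recording",
    "load_recording",
    "write_fits_json",
]

MARKER_COLUMNS = ["sample", "trial", "cue_index"]


@dataclass
class ContinuousRecording:
    """Multichannel signal with cue-onset event markers.

    ``data`` is (n_channels, n_samples); ``markers`` is a DataFrame with
    columns sample (0-based index into the raw signal), trial, cue_index
    (1-based within trial).
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    markers: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch between data and ch_names")
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker table missing columns {missing}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Long-format trial table: one row per cue; chosen/rt on the final row."""
    rows = []
    for tr in trials:
        for i, c in enumerate(tr.cues):
            last = i == len(tr.cues) - 1
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "true_direction": _INT_TO_CUE[tr.true_direction],
                    "cue_index": i + 1,
                    "cue": _INT_TO_CUE[int(c)],
                    "chosen": (_INT_TO_CUE[tr.choice] if tr.choice is not None else "")
                    if last
                    else "",
                    "rt_ms": (round(tr.rt * 1000.0, 3) if tr.rt is not None else "")
                    if last
                    else "",
                }
            )
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for tid, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("cue_index")
        cues = [cue_to_int(c) for c in grp["cue"]]
        last = grp.iloc[-1]
        chosen = last["chosen"]
        choice = cue_to_int(chosen) if isinstance(chosen, str) and chosen in ("L", "R") else None
        rt_ms = last["rt_ms"]
        rt = float(rt_ms) / 1000.0 if rt_ms not in ("", None) and pd.notna(rt_ms) else None
        trials.append(
            TrialRecord(
                trial_id=int(tid),
                true_direction=cue_to_int(last["true_direction"]),
                cues=np.asarray(cues),
                choice=choice,
                rt=rt,
            )
        )
    return trials


def write_trials_csv(trials: Sequence[TrialRecord], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    return frame_to_trials(df)


def save_recording(rec: ContinuousRecording, path: str | Path) -> None:
    """Write raw float32 binary + JSON sidecar (``<path>.json``)."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    sidecar = {
        "fs": rec.fs,
        "ch_names": rec.ch_names,
        "n_samples": int(rec.n_samples),
        "dtype": "<f4",
        "order": "C (channels x samples)",
        "markers": {
            "sample": [int(x) for x in rec.markers["sample"]],
            "trial": [int(x) for x in rec.markers["trial"]],
            "cue_index": [int(x) for x in rec.markers["cue_index"]],
        },
        "meta": rec.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path: str | Path) -> ContinuousRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n_ch = len(sidecar["ch_names"])
    data = np.fromfile(path, dtype="<f4").reshape(n_ch, sidecar["n_samples"])
    markers = pd.DataFrame(sidecar["markers"])
    return ContinuousRecording(
        data=data.astype(float),
        fs=float(sidecar["fs"]),
        ch_names=list(sidecar["ch_names"]),
        markers=markers,
        meta=sidecar.get("meta", {}),
    )


def write_fits_json(fits, path: str | Path) -> None:
    """Serialize a list of ChoiceModelFit objects (ascending BIC) to JSON."""
    payload = [f.to_dict() for f in fits]
    Path(path).write_text(json.dumps(payload, indent=1))
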