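"""File formats and configuration.

All tabular I/O is comma-delimited UTF-8 with header rows; floats serialize
at 6 significant digits.  Coordinates are in cm, amplitudes in mV.  EMG sweep
files carry their sampling metadata on a leading ``#`` line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emg import EMGFrame
from .mapping import GridSpec

__all__ = [
    "PipelineConfig",
    "FLOAT_FORMAT",
    "write_csv",
    "write_emg_dir",
    "read_emg_file",
    "read_emg_dir",
    "write_json",
]

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Settings of one end-to-end run; defaults reproduce the standard protocol."""

    out_dir: str = "out"
    seed: int = 0
    n_experimental: int = 26
    n_control: int = 10
    n_stimuli: int = 90
    grid_width_cm: float = 7.0
    grid_height_cm: float = 5.0
    grid_rows: int = 6
    grid_cols: int = 8
    partitions: int = 50
    mep_window_ms: tuple[float, float] = (10.0, 60.0)
    threshold_fraction: float = 0.25
    band_multiplier: float = 1.0
    alpha: float = 0.05
    with_emg: bool = True
    correlate_on: str = "change"  # "change" | "day2"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.band_multiplier <= 0:
            raise ValueError("band_multiplier must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.mep_window_ms = tuple(float(v) for v in self.mep_window_ms)  # type: ignore[assignment]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            width_cm=self.grid_width_cm, height_cm=self.grid_height_cm,
            rows=self.grid_rows, cols=self.grid_cols, partitions=self.partitions,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mep_window_ms"] = list(self.mep_window_ms)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mep_window_ms" in data:
            data = dict(data, mep_window_ms=tuple(data["mep_window_ms"]))
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_emg_dir(frames: dict, emg_dir) -> list[Path]:
    """Write EMG sweeps, one file per participant-timepoint.

    File layout: a leading ``# sampling_hz=...,stim_onset_index=...`` metadata
    line, then a CSV matrix with one column per trial (header ``trial_<k>``)
    and one row per sample (mV).
    """
    emg_dir = Path(emg_dir)
    emg_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (pid, timepoint), frame_list in sorted(frames.items()):
        if not frame_list:
            continue
        fs = frame_list[0].sampling_rate
        onset = frame_list[0].stim_onset_index
        mat = np.column_stack([f.samples for f in frame_list])
        df = pd.DataFrame(mat, columns=[f"trial_{f.trial}" for f in frame_list])
        path = emg_dir / f"{pid}_{timepoint}.csv"
        with open(path, "w") as fh:
            fh.write(f"# sampling_hz={fs:g},stim_onset_index={onset}\n")
            df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
        written.append(path)
    return written


def read_emg_file(path) -> list[EMGFrame]:
    """Read one participant-timepoint EMG file back into frames."""
    path = Path(path)
    pid, _, timepoint = path.stem.rpartition("_")
    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("#"):
            raise ValueError(f"{path}: missing metadata line")
        meta = dict(kv.split("=") for kv in meta_line.lstrip("# ").strip().split(","))
        df = pd.read_csv(fh)
    fs = float(meta["sampling_hz"])
    onset = int(meta["stim_onset_index"])
    frames = []
    for col in df.columns:
        trial = int(col.rsplit("_", 1)[1])
        frames.append(
            EMGFrame(
                samples=df[col].to_numpy(float), sampling_rate=fs,
                stim_onset_index=onset, participant_id=pid,
                timepoint=timepoint, trial=trial,
            )
        )
    return frames


def read_emg_dir(emg_dir) -> dict[tuple[str, str], list[EMGFrame]]:
    out: dict[tuple[str, str], list[EMGFrame]] = {}
    for path in sorted(Path(emg_dir).glob("*.csv")):
        frames = read_emg_file(path)
        if frames:
            out[(frames[0].participant_id, frames[0].timepoint)] = frames
    return out
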