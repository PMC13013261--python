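"""Reading and writing recordings, manifests and ground truth.

The interchange format is a plain CSV dialect with header
``time_s,abp_mmHg,cbv_cm_s,ecg_mV,etco2_mmHg`` (UTF-8, "." decimal).
Floats are written with Python's shortest round-tripping repr, so a
write/read cycle is bit-identical. Recordings are validated for 200 Hz
sampling and resampled (with a warning) otherwise. EDF input is not
supported in this build; the CSV dialect is the interchange format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .signals import Recording, UniformSignal
from .synth import GroundTruth

__all__ = [
    "CSV_COLUMNS",
    "read_recording",
    "write_recording_csv",
    "write_ground_truth",
    "Epoch",
    "ManifestEntry",
    "Manifest",
]

CSV_COLUMNS = {
    "abp": ("abp_mmHg", "mmHg"),
    "cbv": ("cbv_cm_s", "cm/s"),
    "ecg": ("ecg_mV", "mV"),
    "etco2": ("etco2_mmHg", "mmHg"),
}
TARGET_FS = 200.0


def write_recording_csv(rec: Recording, path) -> None:
    """Write a recording in the canonical CSV dialect (lossless round trip)."""
    n = min(ch.n for ch in rec.channels.values())
    data = {"time_s": np.arange(n) / rec.fs}
    for key, (col, _units) in CSV_COLUMNS.items():
        if key in rec:
            data[col] = rec[key].values[:n]
    pd.DataFrame(data).to_csv(path, index=False)


def _infer_fs(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    return 1.0 / np.median(dt)


def read_recording(path, format: str = "csv") -> Recording:
    """Load a recording; ``abp`` is mandatory, other channels optional.

    Non-200 Hz files are polyphase-resampled to 200 Hz with a warning.
    """
    if format == "edf":
        raise NotImplementedError(
            "EDF input is not supported in this build; convert to the CSV dialect "
            "(time_s,abp_mmHg,cbv_cm_s,ecg_mV,etco2_mmHg)"
        )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("CSV must contain a time_s column")
    col_to_key = {col: key for key, (col, _u) in CSV_COLUMNS.items()}
    present = [c for c in df.columns if c in col_to_key]
    if "abp_mmHg" not in present:
        raise ValueError("mandatory channel abp_mmHg missing")
    fs = _infer_fs(df["time_s"].to_numpy())
    channels = {}
    for col in present:
        key = col_to_key[col]
        values = df[col].to_numpy(dtype=float)
        if abs(fs - TARGET_FS) > 0.5:
            warnings.warn(
                f"{path}: sampling rate {fs:.1f} Hz != {TARGET_FS:.0f} Hz; resampling",
                stacklevel=2,
            )
            up, down = int(round(TARGET_FS)), int(round(fs))
            values = sps.resample_poly(values, up, down)
        channels[key] = UniformSignal(
            values, TARGET_FS, label=key, units=CSV_COLUMNS[key][1]
        )
    return Recording(channels=channels, fs=TARGET_FS)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


@dataclass
class Epoch:
    """One protocol state within a recording: baseline or a paced rate."""

    label: str  # "baseline" | "6" | "10" | "15"
    start_s: float
    end_s: float
    target_bpm: Optional[float] = None

    VALID_LABELS = ("baseline", "6", "10", "15")

    def __post_init__(self) -> None:
        if self.label not in self.VALID_LABELS:
            raise ValueError(f"epoch label must be one of {self.VALID_LABELS}")
        if self.end_s <= self.start_s:
            raise ValueError("epoch end must be after start")


@dataclass
class ManifestEntry:
    participant: str
    path: str
    epochs: List[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = sorted((e.start_s, e.end_s) for e in self.epochs)
        for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping epochs for participant {self.participant}")


@dataclass
class Manifest:
    entries: List[ManifestEntry] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "Manifest":
        raw = yaml.safe_load(Path(path).read_text())
        entries = []
        for item in raw["recordings"]:
            epochs = [
                Epoch(
                    label=str(e["label"]),
                    start_s=float(e["start_s"]),
                    end_s=float(e["end_s"]),
                    target_bpm=e.get("target_bpm"),
                )
                for e in item.get("epochs", [])
            ]
            entries.append(
                ManifestEntry(
                    participant=str(item["participant"]),
                    path=str(item["path"]),
                    epochs=epochs,
                )
            )
        return cls(entries)

    def to_yaml(self, path) -> None:
        payload = {
            "recordings": [
                {
                    "participant": e.participant,
                    "path": e.path,
                    "epochs": [
                        {
                            "label": ep.label,
                            "start_s": ep.start_s,
                            "end_s": ep.end_s,
                            "target_bpm": ep.target_bpm,
                        }
                        for ep in e.epochs
                    ],
                }
                for e in self.entries
            ]
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
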