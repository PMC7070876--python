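"""Readers and writers: recording CSVs, subject metadata, window containers.

Recording CSV layout (header required, columns matched by name):
``timestamp, acc_x, acc_y, acc_z, gyro_x, gyro_y, gyro_z[, activity]``.
Timestamps are seconds and must increase strictly monotonically; the
sampling rate is inferred from the median timestamp increment unless given.

Windowed datasets round-trip through a single ``.npz`` archive holding the
window tensor, labels, subject ids, provenance indices and a JSON metadata
blob (format version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CHANNEL_NAMES, SensorSequence, SubjectMeta, Window

CONTAINER_FORMAT = "motionbmi-windows-v1"


class RecordingError(ValueError):
    """Base class for recording ingestion failures."""


class MissingColumnError(RecordingError):
    pass


class NonMonotoneTimeError(RecordingError):
    pass


class EmptyRecordingError(RecordingError):
    pass


#: best-effort column adapters for common public-dataset layouts; exact
#: layouts vary by dataset release, so these are name maps only
COLUMN_LAYOUTS: dict[str, dict[str, str]] = {
    "generic": {},
    # phone-in-pocket logs with userAcceleration/rotationRate channel names
    "motionsense": {
        "userAcceleration.x": "acc_x",
        "userAcceleration.y": "acc_y",
        "userAcceleration.z": "acc_z",
        "rotationRate.x": "gyro_x",
        "rotationRate.y": "gyro_y",
        "rotationRate.z": "gyro_z",
    },
    # logs carrying a relative-seconds column alongside a raw device timestamp
    "mobiact": {"rel_time": "timestamp"},
}


def read_recording_csv(
    path,
    subject_id: Optional[str] = None,
    sampling_rate_hz: Optional[float] = None,
    delimiter: str = ",",
    strict: bool = True,
    layout: str = "generic",
    column_map: Optional[dict[str, str]] = None,
) -> SensorSequence:
    """Read one subject's recording; rows with unparseable values are
    rejected (with their line numbers) when ``strict=False``, fatal otherwise.

    ``layout`` selects a named column-renaming preset (see
    :data:`COLUMN_LAYOUTS`); ``column_map`` supplies explicit renames and
    wins over the preset. Files without a timestamp column are accepted when
    ``sampling_rate_hz`` is given (timestamps are synthesized).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter)
    if layout not in COLUMN_LAYOUTS:
        raise ValueError(
            f"unknown layout {layout!r}; choose from {sorted(COLUMN_LAYOUTS)}"
        )
    renames = {**COLUMN_LAYOUTS[layout], **(column_map or {})}
    if renames:
        df = df.rename(columns=renames)
    if "timestamp" not in df.columns and sampling_rate_hz is not None:
        df.insert(0, "timestamp", np.arange(len(df)) / sampling_rate_hz)
    if df.shape[0] == 0:
        raise EmptyRecordingError(f"{path}: no data rows")
    required = ("timestamp",) + CHANNEL_NAMES
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    numeric = df[list(required)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        lines = (numeric.index[bad] + 2).tolist()
        if strict:
            raise RecordingError(
                f"{path}: unparseable values on lines {lines}"
            )
        warnings.warn(
            f"{path}: dropped {bad.sum()} corrupt row(s) at lines {lines}",
            RuntimeWarning,
            stacklevel=2,
        )
        numeric = numeric[~bad]
        df = df[~bad]
    if numeric.shape[0] == 0:
        raise EmptyRecordingError(f"{path}: no valid data rows")
    t = numeric["timestamp"].to_numpy()
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise NonMonotoneTimeError(
            f"{path}: timestamps not strictly increasing near line {i + 2}"
        )
    if sampling_rate_hz is None:
        if len(t) < 2:
            raise RecordingError(
                f"{path}: cannot infer sampling rate from a single row"
            )
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))
    activity = None
    if "activity" in df.columns:
        acts = df["activity"].dropna().unique()
        activity = str(acts[0]) if len(acts) else None
    return SensorSequence(
        subject_id=subject_id or path.stem,
        sampling_rate_hz=sampling_rate_hz,
        data=numeric[list(CHANNEL_NAMES)].to_numpy().T,
        activity_label=activity,
    )


def write_recording_csv(seq: SensorSequence, path) -> None:
    t = np.arange(seq.n_samples) / seq.sampling_rate_hz
    df = pd.DataFrame({"timestamp": t})
    for i, name in enumerate(CHANNEL_NAMES):
        df[name] = seq.data[i]
    if seq.activity_label is not None:
        df["activity"] = seq.activity_label
    df.to_csv(path, index=False)


def read_metadata_csv(path, delimiter: str = ",") -> list[SubjectMeta]:
    """Subject table: ``subject_id, height_cm, weight_kg[, bmi]``.

    BMI is computed from height and weight when the column is absent.
    """
    df = pd.read_csv(path, sep=delimiter)
    required = {"subject_id"}
    if not required.issubset(df.columns):
        raise MissingColumnError(f"{path}: missing columns {required - set(df.columns)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SubjectMeta(
                subject_id=str(row["subject_id"]),
                height_cm=float(row["height_cm"]) if "height_cm" in df else None,
                weight_kg=float(row["weight_kg"]) if "weight_kg" in df else None,
                bmi=float(row["bmi"]) if "bmi" in df.columns else None,
            )
        )
    return out


def write_metadata_csv(metas: Sequence[SubjectMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "height_cm": m.height_cm,
                "weight_kg": m.weight_kg,
                "bmi": m.bmi,
            }
            for m in metas
        ]
    ).to_csv(path, index=False)


@dataclass
class WindowDataset:
    """In-memory windowed dataset with provenance, serializable to .npz."""

    tensor: np.ndarray  # (N, 6, w)
    labels: np.ndarray  # (N,)
    subject_ids: np.ndarray  # (N,) str
    window_indices: np.ndarray  # (N,) int
    sampling_rate_hz: float
    metadata: dict

    def __post_init__(self):
        n = self.tensor.shape[0]
        if not (
            len(self.labels) == len(self.subject_ids) == len(self.window_indices) == n
        ):
            raise ValueError("dataset arrays disagree in length")

    def __len__(self) -> int:
        return self.tensor.shape[0]

    @classmethod
    def from_windows(
        cls, windows: Sequence[Window], metadata: Optional[dict] = None
    ) -> "WindowDataset":
        if len(windows) == 0:
            return cls(
                tensor=np.empty((0, 6, 0)),
                labels=np.empty(0),
                subject_ids=np.empty(0, dtype="U1"),
                window_indices=np.empty(0, dtype=int),
                sampling_rate_hz=float("nan"),
                metadata=dict(metadata or {}),
            )
        return cls(
            tensor=np.stack([w.data for w in windows]),
            labels=np.array([w.bmi_label for w in windows]),
            subject_ids=np.array([w.subject_id for w in windows]),
            window_indices=np.array([w.window_index for w in windows]),
            sampling_rate_hz=windows[0].sampling_rate_hz,
            metadata=dict(metadata or {}),
        )

    def to_windows(self) -> list[Window]:
        return [
            Window(
                subject_id=str(self.subject_ids[i]),
                window_index=int(self.window_indices[i]),
                data=self.tensor[i],
                bmi_label=float(self.labels[i]),
                sampling_rate_hz=self.sampling_rate_hz,
            )
            for i in range(len(self))
        ]

    def save(self, path) -> None:
        meta = dict(self.metadata)
        meta["format"] = CONTAINER_FORMAT
        np.savez(
            path,
            tensor=self.tensor,
            labels=self.labels,
            subject_ids=self.subject_ids,
            window_indices=self.window_indices,
            sampling_rate_hz=np.array(self.sampling_rate_hz),
            metadata_json=np.array(json.dumps(meta, sort_keys=True)),
        )

    @classmethod
    def load(cls, path) -> "WindowDataset":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["metadata_json"]))
        fmt = meta.pop("format", None)
        if fmt != CONTAINER_FORMAT:
            raise ValueError(
                f"incompatible window container format {fmt!r} "
                f"(expected {CONTAINER_FORMAT})"
            )
        return cls(
            tensor=data["tensor"],
            labels=data["labels"],
            subject_ids=data["subject_ids"],
            window_indices=data["window_indices"],
            sampling_rate_hz=float(data["sampling_rate_hz"]),
            metadata=meta,
        )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration description."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
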