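"""Accelerometer record / annotation I-O and 10 s epoch segmentation.

A deployment record is a uniformly sampled tri-axial acceleration series
(units of g, gravity included) plus a set of non-overlapping annotation
intervals, each carrying a single behaviour label.  Segmentation cuts the
record into consecutive, non-overlapping windows of ``epoch_s`` seconds,
phase-locked to the record start; a window is retained only if every sample
in it falls inside intervals of one single non-reserved behaviour.  Windows
touching unknown or transitional annotation, windows straddling a behaviour
change, and trailing partial windows are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Behaviour classes: the four activity states observed in each phase of the
#: study (sound = unimpaired gait, lame = impaired gait).
BEHAVIOURS = (
    "sound_grazing",
    "sound_standing",
    "sound_walking",
    "sound_lying",
    "lame_walking",
    "lame_grazing",
    "lame_standing",
    "lame_lying",
)

#: Labels an annotator may use for intervals that must be excluded downstream.
RESERVED_LABELS = ("unknown", "transition")

DEPLOYMENTS = ("ear", "collar", "leg")

ACCEL_COLUMNS = ("time_s", "x_g", "y_g", "z_g")
ANNOTATION_COLUMNS = ("start_s", "end_s", "behaviour")


def phase_of(behaviour: str) -> str:
    """Observation phase of a behaviour label: 'sound', 'lame', or 'reserved'."""
    if behaviour in RESERVED_LABELS:
        return "reserved"
    return behaviour.split("_", 1)[0]


@dataclass
class AccelSeries:
    """A uniformly sampled tri-axial acceleration record for one deployment.

    Attributes
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing, uniform spacing
        consistent with ``rate_hz`` within 1e-6 s.
    x, y, z : ndarray
        Per-sample acceleration in g along the three orthogonal sensor axes.
    rate_hz : float
        Sampling rate in Hz.
    animal_id : str
    deployment : str
        Attachment site: 'ear', 'collar', or 'leg'.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate_hz: float
    animal_id: str = "unknown"
    deployment: str = "ear"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("times/x/y/z must have equal lengths")
        if n == 0:
            raise ValueError("empty series")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(f"times not strictly increasing at sample {i + 1}")
            if np.any(np.abs(dt - 1.0 / self.rate_hz) > 1e-6):
                i = int(np.argmax(np.abs(dt - 1.0 / self.rate_hz) > 1e-6))
                raise ValueError(
                    f"non-uniform sample spacing at sample {i + 1}: "
                    f"dt={dt[i]:.9g}s vs expected {1.0 / self.rate_hz:.9g}s"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def samples(self) -> np.ndarray:
        """(n, 3) array of stacked x/y/z samples."""
        return np.column_stack([self.x, self.y, self.z])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "x_g": self.x, "y_g": self.y, "z_g": self.z}
        )


@dataclass
class Annotation:
    """One annotated interval [start_s, end_s) with a single behaviour label."""

    start_s: float
    end_s: float
    behaviour: str
    animal_id: str = "unknown"
    phase: str = ""
    deployment: str = "ear"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"annotation interval must have start < end, got "
                f"[{self.start_s}, {self.end_s})"
            )
        if self.behaviour not in BEHAVIOURS and self.behaviour not in RESERVED_LABELS:
            raise ValueError(f"unrecognized behaviour label {self.behaviour!r}")
        if not self.phase:
            self.phase = phase_of(self.behaviour)


@dataclass
class AnnotatedEpoch:
    """One fixed-length window of samples carrying a single behaviour label."""

    samples: np.ndarray  # (T, 3), g
    behaviour: str
    animal_id: str
    deployment: str
    start_time: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("epoch samples must be a (T, 3) array")
        if self.samples.shape[0] == 0:
            raise ValueError("epoch must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def read_accel_csv(path, rate_hz: float, animal_id: str = "unknown",
                   deployment: str = "ear") -> AccelSeries:
    """Read a delimited acceleration record (columns time_s, x_g, y_g, z_g).

    Malformed rows are reported with their file line number (header is
    line 1).  Rejects missing columns, non-numeric cells, and non-monotone
    timestamps.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    values = {}
    for col in ACCEL_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        bad |= df[col].isna()
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        values[col] = converted.to_numpy(dtype=float)
    t = values["time_s"]
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.argmax(dt <= 0)) + 3  # offending (later) row
            raise ValueError(f"{path}: non-increasing timestamp at line {line}")
    return AccelSeries(
        times=t, x=values["x_g"], y=values["y_g"], z=values["z_g"],
        rate_hz=rate_hz, animal_id=animal_id, deployment=deployment,
    )


def read_annotations(path) -> list[Annotation]:
    """Read behaviour annotation intervals; returns them sorted by start.

    Intervals labelled 'unknown' or 'transition' are retained (segmentation
    excludes the epochs they touch).  Overlapping intervals are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    anns = []
    for i, row in df.iterrows():
        anns.append(
            Annotation(
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                behaviour=str(row["behaviour"]),
                animal_id=str(row["animal_id"]) if "animal_id" in df.columns else "unknown",
                phase=str(row["phase"]) if "phase" in df.columns else "",
                deployment=str(row["deployment"]) if "deployment" in df.columns else "ear",
            )
        )
    anns.sort(key=lambda a: a.start_s)
    for prev, cur in zip(anns, anns[1:]):
        if cur.start_s < prev.end_s - 1e-9:
            raise ValueError(
                f"{path}: overlapping annotation intervals "
                f"[{prev.start_s}, {prev.end_s}) and [{cur.start_s}, {cur.end_s})"
            )
    return anns


def _sample_labels(series: AccelSeries, annotations: list[Annotation]) -> np.ndarray:
    """Label every sample with its interval's behaviour ('' = unannotated)."""
    labels = np.full(len(series), "", dtype=object)
    t = series.times
    for ann in annotations:
        inside = (t >= ann.start_s - 1e-9) & (t < ann.end_s - 1e-9)
        labels[inside] = ann.behaviour
    return labels


def segment_epochs(series: AccelSeries, annotations: list[Annotation],
                   epoch_s: float = 10.0) -> list[AnnotatedEpoch]:
    """Cut a record into single-behaviour epochs of ``epoch_s`` seconds.

    Windows are consecutive, non-overlapping, and phase-locked to the record
    start.  A window is kept iff all of its samples carry one identical,
    non-reserved behaviour label; mixed, unannotated, unknown, and
    transitional windows are excluded, as is any trailing partial window.
    """
    t_float = epoch_s * series.rate_hz
    T = round(t_float)
    if abs(t_float - T) > 1e-9 or T <= 0:
        raise ValueError(
            f"epoch_s * rate_hz = {t_float!r} is not a positive integer "
            "sample count; adjust the epoch length or sampling rate"
        )
    labels = _sample_labels(series, annotations)
    xyz = series.samples
    epochs: list[AnnotatedEpoch] = []
    n_windows = len(series) // T
    for k in range(n_windows):
        sl = slice(k * T, (k + 1) * T)
        window_labels = labels[sl]
        first = window_labels[0]
        if first == "" or first in RESERVED_LABELS:
            continue
        if not all(l == first for l in window_labels):
            continue
        epochs.append(
            AnnotatedEpoch(
                samples=xyz[sl],
                behaviour=first,
                animal_id=series.animal_id,
                deployment=series.deployment,
                start_time=float(series.times[k * T]),
            )
        )
    return epochs


def write_accel_csv(series: AccelSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.9g")


def write_annotations(annotations: list[Annotation], path) -> None:
    df = pd.DataFrame(
        [
            {
                "start_s": a.start_s,
                "end_s": a.end_s,
                "behaviour": a.behaviour,
                "animal_id": a.animal_id,
                "phase": a.phase,
                "deployment": a.deployment,
            }
            for a in annotations
        ]
    )
    df.to_csv(path, index=False, float_format="%.9g")
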