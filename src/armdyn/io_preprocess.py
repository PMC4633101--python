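"""Recording containers, CSV I/O, high-pass filtering and isolated joint series.

A recording holds the trajectories of five markers along the arm -- the tip of
the pointing rod, finger, wrist, elbow and shoulder -- each with X, Y and Z
components sampled at a fixed rate (100 Hz by default, 2000 samples = 20 s).
The coordinate convention has Z vertical and Y pointing toward the target, so
the Y direction is the one the pointing task leaves unconstrained.

The *isolated series* of joint ``i`` is the difference between the adjacent,
more distal marker and the joint itself, ``Δs^i = s^{i-1} - s^i``; it removes
the motion the joint merely inherits from its proximal neighbour and keeps the
contribution of the joint's own rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

MARKERS = ("rod", "finger", "wrist", "elbow", "shoulder")
COMPONENTS = ("X", "Y", "Z")

#: S1-layout column order: rod XYZ, finger XYZ, wrist XYZ, elbow XYZ, shoulder XYZ.
S1_COLUMNS = tuple(f"{m}_{c}" for m in MARKERS for c in COMPONENTS)


class LayoutError(ValueError):
    """Input table does not have the 15-column marker layout."""


class RecordingParseError(ValueError):
    """Input table contains a non-numeric or non-finite cell."""


class LengthError(ValueError):
    """Series or table too short for the requested operation."""


@dataclass(frozen=True)
class ComponentSeries:
    """A single scalar channel ``s_alpha^i(t)``."""

    values: np.ndarray
    sampling_rate: float
    label: tuple[str, str] = ("", "")
    filtered: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise LengthError("component series needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise RecordingParseError("component series contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class IsolatedSeries:
    """Isolated joint dynamics ``Δs_alpha^i``; joint 1 (rod) is the bare series."""

    values: np.ndarray
    joint_index: int
    component: str
    sampling_rate: float

    def as_component(self, filtered: bool = False) -> ComponentSeries:
        label = (f"Δ{MARKERS[self.joint_index - 1]}", self.component)
        return ComponentSeries(self.values, self.sampling_rate, label, filtered)


@dataclass
class KinematicRecording:
    """One subject's 5-marker x 3-component trajectory block.

    ``series`` has shape (5, 3, n_samples) with markers in proximal-to-distal
    spec order rod, finger, wrist, elbow, shoulder and components X, Y, Z.
    """

    series: np.ndarray
    sampling_rate: float = 100.0
    subject_id: str = ""
    group_label: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.series, dtype=float)
        if arr.ndim != 3 or arr.shape[:2] != (5, 3):
            raise LayoutError(
                f"series must have shape (5, 3, n_samples); got {arr.shape}"
            )
        if arr.shape[2] < 2:
            raise LengthError("recording must contain at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise RecordingParseError("recording contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.series = arr

    @property
    def n_samples(self) -> int:
        return self.series.shape[2]

    def channel(self, marker: str | int, component: str | int) -> ComponentSeries:
        i = MARKERS.index(marker) if isinstance(marker, str) else int(marker)
        j = COMPONENTS.index(component) if isinstance(component, str) else int(component)
        return ComponentSeries(
            self.series[i, j], self.sampling_rate, (MARKERS[i], COMPONENTS[j])
        )


def read_recording(
    path: str | Path,
    layout: str = "s1_csv",
    sampling_rate: float = 100.0,
    subject_id: str | None = None,
    group_label: str = "unknown",
) -> KinematicRecording:
    """Read a 15-column CSV in the S1 layout (rod/finger/wrist/elbow/shoulder XYZ).

    A header row of the canonical column names is accepted and skipped; the
    sampling rate is not stored in the file and defaults to 100 Hz.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, skip_blank_lines=True, comment="#")
    except pd.errors.EmptyDataError:
        raise LengthError(f"{path}: empty file") from None
    if df.shape[0] and isinstance(df.iloc[0, 0], str):
        # tolerate a single header line
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] != 15:
        raise LayoutError(f"{path}: expected 15 columns, found {df.shape[1]}")
    if df.shape[0] < 2:
        raise LengthError(f"{path}: need at least 2 rows, found {df.shape[0]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise RecordingParseError(
            f"{path}: non-numeric cell at row {r + 1}, column {c + 1}"
        ) from None
    arr = values.T.reshape(5, 3, -1)
    return KinematicRecording(
        arr,
        sampling_rate=sampling_rate,
        subject_id=subject_id or path.stem,
        group_label=group_label,
    )


def write_recording(recording: KinematicRecording, path: str | Path, header: bool = True) -> None:
    """Write a recording as S1-layout CSV (full float precision, round-trip safe)."""
    flat = recording.series.reshape(15, -1).T
    df = pd.DataFrame(flat, columns=list(S1_COLUMNS))
    df.to_csv(path, index=False, header=header, float_format="%.17g")


def write_config(params: dict, path: str | Path) -> None:
    """Sidecar key=value echo of the parameters a recording was produced with."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in params.items():
            fh.write(f"{key}={val}\n")


def highpass_filter(series: ComponentSeries, cutoff: float = 0.5, order: int = 4) -> ComponentSeries:
    """Zero-phase Butterworth high-pass; removes DC and slow drift.

    Applied forward and backward (``filtfilt``) so downstream Hilbert phases
    are not distorted by filter phase lag.
    """
    nyq = series.sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must be in (0, {nyq}) Hz; got {cutoff}")
    sos = signal.butter(order, cutoff, btype="highpass", fs=series.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, series.values)
    return replace(series, values=out, filtered=True)


def filter_recording(recording: KinematicRecording, cutoff: float = 0.5) -> KinematicRecording:
    """High-pass every channel of a recording."""
    out = np.empty_like(recording.series)
    for i in range(5):
        for j in range(3):
            out[i, j] = highpass_filter(
                recording.channel(i, j), cutoff=cutoff
            ).values
    filtered = replace_recording(recording, out)
    filtered.meta = dict(recording.meta, highpass_cutoff_hz=cutoff)
    return filtered


def replace_recording(recording: KinematicRecording, series: np.ndarray) -> KinematicRecording:
    return KinematicRecording(
        series,
        sampling_rate=recording.sampling_rate,
        subject_id=recording.subject_id,
        group_label=recording.group_label,
        meta=dict(recording.meta),
    )


def isolated_series(
    recording: KinematicRecording, joint_index: int, component: str | int
) -> IsolatedSeries:
    """Isolated dynamics of joint ``i``: ``Δs^i = s^{i-1} - s^i`` for i >= 2.

    For the rod (i = 1) there is no more-distal marker; the target is static,
    so the bare rod series is used (its offset vanishes after high-pass).
    """
    if joint_index not in range(1, 6):
        raise ValueError(f"joint_index must be in 1..5; got {joint_index}")
    j = COMPONENTS.index(component) if isinstance(component, str) else int(component)
    if joint_index == 1:
        values = recording.series[0, j].copy()
    else:
        values = recording.series[joint_index - 2, j] - recording.series[joint_index - 1, j]
    return IsolatedSeries(values, joint_index, COMPONENTS[j], recording.sampling_rate)
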