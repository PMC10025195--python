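"""Data model and text I/O for multi-sensor IMU recordings of a TUG trial.

A recording bundles ten body-worn inertial sensors sampled at 100 Hz. Each
sensor stream carries a tri-axial accelerometer (units of g, hard range
±16 g) and a tri-axial gyroscope (deg/s, hard range ±2000 deg/s). The body
frame is fixed throughout the package: x anterior, y left-lateral,
z superior, rotations right-handed about the same axes — so gyro y is the
sagittal (pitch) rate and gyro z the yaw rate.

On disk a recording is one flat CSV: a few ``# key: value`` header lines
(subject id, label, sampling rate) followed by one column per
``placement.channel.axis`` triplet and one row per sample; time is implicit
from the 100 Hz rate and the 0-based row index.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InvariantError,
    MissingSensorError,
    RangeError,
    TimebaseError,
)

#: The ten sensor placements, in canonical order.
PLACEMENTS: tuple[str, ...] = (
    "left_wrist",
    "right_wrist",
    "chest",
    "waist",
    "left_thigh",
    "right_thigh",
    "left_shank",
    "right_shank",
    "left_foot",
    "right_foot",
)

AXES = ("x", "y", "z")
CHANNELS = ("accel", "gyro")

SAMPLING_RATE = 100.0  # Hz
ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0

LABELS = ("PD", "ET", "UNKNOWN")


@dataclasses.dataclass
class SensorStream:
    """One sensor's synchronized accelerometer and gyroscope streams.

    ``accel`` and ``gyro`` are (3, N) arrays; row order is (x, y, z).
    """

    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.accel.shape[1]


@dataclasses.dataclass
class SensorRecording:
    """One subject's 10-sensor TUG recording on a shared 100 Hz timebase."""

    subject_id: str
    label: str
    sensors: dict[str, SensorStream]
    sampling_rate: float = SAMPLING_RATE

    @property
    def n_samples(self) -> int:
        first = next(iter(self.sensors.values()))
        return first.n_samples

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sampling_rate

    def gyro(self, placement: str, axis: str) -> np.ndarray:
        return self.sensors[placement].gyro[AXES.index(axis)]

    def accel(self, placement: str, axis: str) -> np.ndarray:
        return self.sensors[placement].accel[AXES.index(axis)]


@dataclasses.dataclass
class ValidationIssue:
    kind: str  # "MissingSensorError" | "TimebaseError" | "RangeError" | ...
    message: str


@dataclasses.dataclass
class ValidationReport:
    issues: list[ValidationIssue] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def kinds(self) -> list[str]:
        return [i.kind for i in self.issues]


def validate_recording(rec: SensorRecording) -> ValidationReport:
    """Check every data-model invariant; report-only, never raises or mutates."""
    report = ValidationReport()

    if rec.label not in LABELS:
        report.issues.append(
            ValidationIssue("InvariantError", f"unknown label {rec.label!r}")
        )
    if rec.sampling_rate != SAMPLING_RATE:
        report.issues.append(
            ValidationIssue(
                "TimebaseError", f"sampling rate {rec.sampling_rate} != {SAMPLING_RATE}"
            )
        )

    for placement in PLACEMENTS:
        if placement not in rec.sensors:
            report.issues.append(
                ValidationIssue("MissingSensorError", f"missing sensor {placement!r}")
            )
    extra = set(rec.sensors) - set(PLACEMENTS)
    for placement in sorted(extra):
        report.issues.append(
            ValidationIssue("InvariantError", f"unknown placement {placement!r}")
        )

    lengths = set()
    for placement, stream in rec.sensors.items():
        if stream.accel.shape[0] != 3 or stream.gyro.shape[0] != 3:
            report.issues.append(
                ValidationIssue(
                    "InvariantError", f"{placement}: streams must be 3×N arrays"
                )
            )
            continue
        if stream.accel.shape[1] != stream.gyro.shape[1]:
            report.issues.append(
                ValidationIssue(
                    "TimebaseError",
                    f"{placement}: accel N={stream.accel.shape[1]} != "
                    f"gyro N={stream.gyro.shape[1]}",
                )
            )
        lengths.add(stream.accel.shape[1])
        lengths.add(stream.gyro.shape[1])

        for channel, data, bound in (
            ("accel", stream.accel, ACCEL_RANGE_G),
            ("gyro", stream.gyro, GYRO_RANGE_DPS),
        ):
            if not np.all(np.isfinite(data)):
                report.issues.append(
                    ValidationIssue(
                        "InvariantError", f"{placement}.{channel}: non-finite samples"
                    )
                )
                continue
            bad = np.argwhere(np.abs(data) > bound)
            if bad.size:
                ax_i, idx = bad[0]
                report.issues.append(
                    ValidationIssue(
                        "RangeError",
                        f"{placement}.{channel}.{AXES[ax_i]}[{idx}] = "
                        f"{data[ax_i, idx]:g} exceeds ±{bound:g}",
                    )
                )

    if len(lengths) > 1:
        report.issues.append(
            ValidationIssue(
                "TimebaseError", f"streams have unequal lengths: {sorted(lengths)}"
            )
        )
    if lengths == {0}:
        report.issues.append(ValidationIssue("FormatError", "empty streams (N=0)"))
    return report


def _raise_first(report: ValidationReport) -> None:
    """Translate the first validation issue into its exception type."""
    issue = report.issues[0]
    if issue.kind == "MissingSensorError":
        raise MissingSensorError(issue.message.split("'")[1])
    if issue.kind == "TimebaseError":
        raise TimebaseError(issue.message)
    if issue.kind == "RangeError":
        raise RangeError(*_parse_range_message(issue.message))
    if issue.kind == "FormatError":
        raise FormatError(issue.message)
    raise InvariantError(issue.message)


def _parse_range_message(msg: str) -> tuple[str, str, str, int, float]:
    head, _, tail = msg.partition(" = ")
    loc, _, idx = head.partition("[")
    placement, channel, axis = loc.split(".")
    return placement, channel, axis, int(idx.rstrip("]")), float(tail.split()[0])


def _column(placement: str, channel: str, axis: str) -> str:
    return f"{placement}.{channel}.{axis}"


def write_recording(rec: SensorRecording, path: str | Path) -> None:
    """Write a recording to CSV, lossless to better than 1e-9.

    Refuses invalid recordings (including empty streams) so that everything
    on disk round-trips through :func:`read_recording`.
    """
    report = validate_recording(rec)
    if not report.ok:
        _raise_first(report)
    if rec.n_samples == 0:
        raise FormatError("refusing to write empty recording (N=0)")

    path = Path(path)
    columns = {}
    for placement in PLACEMENTS:
        stream = rec.sensors[placement]
        for channel in CHANNELS:
            data = stream.accel if channel == "accel" else stream.gyro
            for ax_i, axis in enumerate(AXES):
                columns[_column(placement, channel, axis)] = data[ax_i]
    frame = pd.DataFrame(columns)
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# label: {rec.label}\n")
        fh.write(f"# sampling_rate: {rec.sampling_rate:g}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def read_recording(path: str | Path) -> SensorRecording:
    """Read and validate one recording CSV."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        try:
            frame = pd.read_csv(fh)
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise FormatError(f"cannot parse {path}: {exc}") from exc

    if frame.shape[0] == 0:
        raise FormatError(f"{path}: no samples")
    rate = float(meta.get("sampling_rate", SAMPLING_RATE))
    if rate != SAMPLING_RATE:
        raise TimebaseError(f"{path}: sampling rate {rate} != {SAMPLING_RATE}")

    sensors: dict[str, SensorStream] = {}
    for placement in PLACEMENTS:
        wanted = [
            _column(placement, channel, axis) for channel in CHANNELS for axis in AXES
        ]
        if any(col not in frame.columns for col in wanted):
            raise MissingSensorError(placement)
        accel = frame[[_column(placement, "accel", a) for a in AXES]].to_numpy().T
        gyro = frame[[_column(placement, "gyro", a) for a in AXES]].to_numpy().T
        sensors[placement] = SensorStream(accel=accel, gyro=gyro)

    rec = SensorRecording(
        subject_id=meta.get("subject_id", path.stem),
        label=meta.get("label", "UNKNOWN"),
        sensors=sensors,
        sampling_rate=rate,
    )
    report = validate_recording(rec)
    if not report.ok:
        _raise_first(report)
    return rec


def new_recording(
    subject_id: str, label: str, streams: Mapping[str, SensorStream]
) -> SensorRecording:
    """Convenience constructor that validates eagerly."""
    rec = SensorRecording(subject_id=subject_id, label=label, sensors=dict(streams))
    report = validate_recording(rec)
    if not report.ok:
        _raise_first(report)
    return rec
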