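"""Partition a TUG recording into its six phases and detect gait cycles.

The trial is segmented from two trunk channels alone:

* turns — low-pass filtered waist yaw rate; a candidate interval is a
  sustained excursion of |yaw rate| above threshold whose edges are then
  relaxed outward to the nearest local minimum of the filtered magnitude,
  accepted when the cumulative yaw is a plausible half-turn (120–240°);
* postural transitions — low-pass filtered chest pitch rate; the first
  sustained excursion before the first turn is the sit-to-stand, the last
  one after the second turn is the stand-to-sit;
* straight walks — the residual intervals between those four events.

Gait cycles come from the shank sagittal gyro: mid-swing is a prominent
positive peak, the zero crossing after it is the heel strike and the zero
crossing before it the toe off. All thresholds are keyword-configurable;
the defaults are tuned for the synthetic templates and ordinary adult gait.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .errors import SegmentationError
from .sensor_io import SAMPLING_RATE, SensorRecording
from .synthetic import COMPONENT_PHASES, PHASE_NAMES

FS = int(SAMPLING_RATE)


@dataclasses.dataclass(frozen=True)
class PhaseInterval:
    """Half-open, 0-based sample interval of one named phase."""

    name: str
    start: int
    end: int

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    @property
    def duration(self) -> float:
        return self.n_samples / FS


@dataclasses.dataclass
class TUGSegments:
    """The six ordered phases of one TUG trial."""

    phases: dict[str, PhaseInterval]

    #: phase → component name, fixed across the package
    COMPONENT_OF = {
        phase: comp for comp, names in COMPONENT_PHASES.items() for phase in names
    }

    def __getitem__(self, name: str) -> PhaseInterval:
        return self.phases[name]

    def ordered(self) -> list[PhaseInterval]:
        return [self.phases[name] for name in PHASE_NAMES]

    def component(self, name: str) -> list[PhaseInterval]:
        return [self.phases[p] for p in COMPONENT_PHASES[name]]


@dataclasses.dataclass(frozen=True)
class GaitCycle:
    leg: str
    heel_strike: int
    toe_off: int
    next_heel_strike: int

    @property
    def gct(self) -> float:
        """Gait cycle time (heel strike to next ipsilateral heel strike), s."""
        return (self.next_heel_strike - self.heel_strike) / FS

    @property
    def swing_fraction(self) -> float:
        return (self.next_heel_strike - self.toe_off) / (
            self.next_heel_strike - self.heel_strike
        )


def _lowpass(x: np.ndarray, cutoff_hz: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, cutoff_hz, btype="low", fs=FS, output="sos")
    return signal.sosfiltfilt(sos, x)


def _relax_edges(mag: np.ndarray, start: int, end: int, floor: float) -> tuple[int, int]:
    """Walk interval edges outward while the magnitude keeps falling.

    Stops at the first local minimum or once the signal drops below
    ``floor``; keeps detected boundaries close to the true onset/offset of
    smooth pulses without bleeding into neighbouring activity.
    """
    s = start
    while s > 0 and mag[s - 1] <= mag[s] and mag[s] > floor:
        s -= 1
    e = end
    while e < len(mag) - 1 and mag[e + 1] <= mag[e] and mag[e] > floor:
        e += 1
    return s, e + 1


def _sustained_intervals(
    above: np.ndarray, min_samples: int, merge_gap: int
) -> list[tuple[int, int]]:
    """Maximal runs of True, merged across short gaps, length-filtered."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > merge_gap)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_samples]


def detect_turns(
    rec: SensorRecording,
    *,
    yaw_cutoff_hz: float = 1.5,
    rate_threshold: float = 15.0,
    min_duration_s: float = 0.5,
    floor: float = 1.5,
    yaw_bounds: tuple[float, float] = (120.0, 240.0),
) -> list[PhaseInterval]:
    """Find ≈180° turns from the waist yaw rate; sorted, possibly empty."""
    yaw = _lowpass(rec.gyro("waist", "z"), yaw_cutoff_hz)
    mag = np.abs(yaw)
    candidates = _sustained_intervals(
        mag > rate_threshold,
        min_samples=int(min_duration_s * FS),
        merge_gap=int(0.2 * FS),
    )
    turns = []
    for s, e in candidates:
        s, e = _relax_edges(mag, s, e - 1, floor)
        total = abs(np.sum(yaw[s:e])) / FS
        if yaw_bounds[0] <= total <= yaw_bounds[1]:
            turns.append(PhaseInterval("turn", s, e))
    return sorted(turns, key=lambda p: p.start)


def _detect_transition(
    pitch_mag: np.ndarray,
    lo: int,
    hi: int,
    which: str,
    *,
    rate_threshold: float,
    min_duration_s: float,
    floor: float,
) -> tuple[int, int] | None:
    window = pitch_mag[lo:hi]
    events = _sustained_intervals(
        window > rate_threshold,
        min_samples=int(min_duration_s * FS),
        merge_gap=int(0.25 * FS),
    )
    if not events:
        return None
    s, e = events[0] if which == "first" else events[-1]
    s, e = _relax_edges(pitch_mag, lo + s, lo + e - 1, floor)
    return max(s, lo), min(e, hi)


def segment_tug(
    rec: SensorRecording,
    *,
    yaw_cutoff_hz: float = 1.5,
    turn_rate_threshold: float = 15.0,
    pitch_cutoff_hz: float = 5.0,
    pitch_rate_threshold: float = 15.0,
    transition_min_duration_s: float = 0.3,
    floor: float = 1.5,
) -> TUGSegments:
    """Segment one full TUG trial into its six contiguous phases.

    Raises :class:`SegmentationError` with reason ``"turn_count"`` when the
    recording does not contain exactly two qualifying turns, and
    ``"no_standing"`` / ``"no_sitting"`` when a postural transition cannot
    be located.
    """
    turns = detect_turns(
        rec,
        yaw_cutoff_hz=yaw_cutoff_hz,
        rate_threshold=turn_rate_threshold,
        floor=floor,
    )
    if len(turns) != 2:
        raise SegmentationError("turn_count", f"found {len(turns)} turns, need 2")
    turn1, turn2 = turns

    pitch_mag = np.abs(_lowpass(rec.gyro("chest", "y"), pitch_cutoff_hz))
    s2s = _detect_transition(
        pitch_mag,
        0,
        turn1.start,
        "first",
        rate_threshold=pitch_rate_threshold,
        min_duration_s=transition_min_duration_s,
        floor=floor,
    )
    if s2s is None:
        raise SegmentationError("no_standing", "no sit-to-stand before first turn")
    sts = _detect_transition(
        pitch_mag,
        turn2.end,
        rec.n_samples,
        "last",
        rate_threshold=pitch_rate_threshold,
        min_duration_s=transition_min_duration_s,
        floor=floor,
    )
    if sts is None:
        raise SegmentationError("no_sitting", "no stand-to-sit after last turn")

    if not (s2s[1] <= turn1.start < turn1.end <= turn2.start < turn2.end <= sts[0]):
        raise SegmentationError("phase_order", "detected events out of order")

    # stitch into six contiguous phases; the short gap between the second
    # turn and the stand-to-sit is split at its midpoint
    mid = (turn2.end + sts[0]) // 2
    boundaries = [s2s[0], s2s[1], turn1.start, turn1.end, turn2.start, mid, sts[1]]
    phases = {
        name: PhaseInterval(name, int(boundaries[i]), int(boundaries[i + 1]))
        for i, name in enumerate(PHASE_NAMES)
    }
    for interval in phases.values():
        if interval.duration < 0.3:
            raise SegmentationError(
                "short_phase", f"{interval.name} lasts {interval.duration:.2f} s"
            )
    return TUGSegments(phases=phases)


def detect_gait_cycles(
    rec: SensorRecording,
    walk: PhaseInterval,
    *,
    cutoff_hz: float = 6.0,
    min_peak_height: float = 80.0,
    min_stride_s: float = 0.6,
    guard_s: float = 0.2,
) -> list[GaitCycle]:
    """Per-leg gait cycles within one walk phase (may be empty).

    A 0.2 s guard band at each end of the phase is ignored so transition
    motion does not contaminate the first/last cycle.
    """
    lo = walk.start + int(guard_s * FS)
    hi = walk.end - int(guard_s * FS)
    if hi - lo < int(min_stride_s * FS):
        return []
    cycles: list[GaitCycle] = []
    for leg in ("left", "right"):
        x = _lowpass(rec.gyro(f"{leg}_shank", "y"), cutoff_hz)[lo:hi]
        peaks, _ = signal.find_peaks(
            x, height=min_peak_height, distance=int(min_stride_s * FS)
        )
        events = []  # (heel_strike, toe_off_of_previous_cycle)
        for p in peaks:
            after = np.flatnonzero(x[p:] <= 0.0)
            before = np.flatnonzero(x[:p] <= 0.0)
            if after.size == 0 or before.size == 0:
                continue
            heel_strike = p + int(after[0])
            toe_off = int(before[-1])
            events.append((heel_strike, toe_off))
        for (hs, _), (next_hs, next_to) in zip(events, events[1:]):
            if hs < next_to < next_hs:
                cycles.append(
                    GaitCycle(
                        leg=leg,
                        heel_strike=lo + hs,
                        toe_off=lo + next_to,
                        next_heel_strike=lo + next_hs,
                    )
                )
    return sorted(cycles, key=lambda c: (c.leg, c.heel_strike))


def write_segments_tsv(subject_id: str, seg: TUGSegments, path) -> None:
    """BED-like TSV: subject, phase, start, end, component."""
    import pandas as pd

    rows = [
        {
            "subject_id": subject_id,
            "phase": p.name,
            "start_sample": p.start,
            "end_sample": p.end,
            "component": TUGSegments.COMPONENT_OF[p.name],
        }
        for p in seg.ordered()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
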