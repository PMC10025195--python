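"""Gait and postural-transition parameters from a segmented TUG recording.

The catalogue is registry-based: each feature has a name, a component tag
(standing, straight_walk, turning, sitting) and an extractor over a shared
per-subject context. Lateral (left/right) quantities are resolved into the
Max / Min / abs convention: the larger of the pair, the smaller of the
pair, and the absolute left-right difference. Trunk pitch angles are
obtained by integrating the chest sagittal gyro with a linear drift
correction anchored at the phase endpoints (assumed static); the backward
direction is positive.

The arm symbolic symmetry index summarizes left/right arm-swing symmetry:
per-swing excursions of each wrist's integrated sagittal angle are
symbolized into an 8-letter alphabet by equal-width binning over the
pooled two-arm range, and the index is the total-variation distance
between the two symbol distributions — 0 for identical distributions,
bounded by 1, increasing with asymmetry.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InsufficientCyclesError, SchemaError
from .segmentation import (
    FS,
    GaitCycle,
    PhaseInterval,
    TUGSegments,
    detect_gait_cycles,
    _lowpass,
)
from .sensor_io import SensorRecording

N_SYMBOLS = 8  # alphabet size for the symmetry index
MIN_CYCLES = 3


def resolve_lateral_pairs(left_value: float, right_value: float) -> dict[str, float]:
    """Max/Min/abs convention for a left/right parameter pair."""
    if not (math.isfinite(left_value) and math.isfinite(right_value)):
        raise ValueError("lateral pair values must be finite")
    return {
        "Max": max(left_value, right_value),
        "Min": min(left_value, right_value),
        "abs": abs(left_value - right_value),
    }


def symbolize(values: Sequence[float], edges: np.ndarray) -> np.ndarray:
    """Map values to symbol indices 0..len(edges)-2 (equal-width bins)."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def symbolic_symmetry_index(
    left: Sequence[float], right: Sequence[float], n_symbols: int = N_SYMBOLS
) -> float:
    """Total-variation distance between symbolized arm-swing distributions.

    Requires at least three swings per side. 0 iff both empirical symbol
    distributions coincide; 1 when they are disjoint.
    """
    # quantize at 1e-9 deg so float jitter cannot flip a bin assignment
    left = np.round(np.asarray(left, dtype=float), 9)
    right = np.round(np.asarray(right, dtype=float), 9)
    if left.size < MIN_CYCLES or right.size < MIN_CYCLES:
        raise InsufficientCyclesError(
            f"need >= {MIN_CYCLES} swings per arm, got {left.size}/{right.size}"
        )
    lo = min(left.min(), right.min())
    hi = max(left.max(), right.max())
    if hi == lo:  # all swings identical on both sides
        return 0.0
    edges = np.linspace(lo, hi, n_symbols + 1)
    p = np.bincount(symbolize(left, edges), minlength=n_symbols) / left.size
    q = np.bincount(symbolize(right, edges), minlength=n_symbols) / right.size
    return float(0.5 * np.abs(p - q).sum())


def integrate_pitch(rec: SensorRecording, phase: PhaseInterval) -> np.ndarray:
    """Trunk pitch angle (deg, backward positive) over a phase.

    Integrates the chest sagittal gyro and removes a linear drift anchored
    at the phase endpoints, which are assumed static.
    """
    rate = rec.gyro("chest", "y")[phase.start : phase.end]
    angle = np.cumsum(rate) / FS
    if angle.size > 1:
        drift = np.linspace(0.0, angle[-1], angle.size)
        angle = angle - drift
    return angle


def turn_kinematics(
    rec: SensorRecording, turn: PhaseInterval, smooth_s: float = 0.15
) -> dict[str, float]:
    """Duration and mean/max |yaw rate| of one turning phase.

    The yaw rate is smoothed with a positive (moving-average) kernel so the
    reported maximum cannot overshoot the true plateau the way a sharp IIR
    low-pass would.
    """
    from scipy.ndimage import uniform_filter1d

    width = max(1, int(smooth_s * FS))
    yaw = np.abs(
        uniform_filter1d(rec.gyro("waist", "z"), size=width)[turn.start : turn.end]
    )
    return {
        "duration": turn.duration,
        "mean_angular_velocity": float(yaw.mean()),
        "max_angular_velocity": float(yaw.max()),
    }


def transition_kinematics(
    rec: SensorRecording,
    phase: PhaseInterval,
    kind: str,
    cutoff_hz: float = 8.0,
) -> dict[str, float]:
    """Trunk kinematics of a sit-to-stand or stand-to-sit phase.

    ``max_sagittal_angular_velocity`` is the absolute peak of the filtered
    chest pitch rate; for stand-to-sit, ``min_lean_angle`` is the peak
    backward tilt (backward positive, forward negative) of the integrated
    trunk pitch.
    """
    if kind not in ("sit_to_stand", "stand_to_sit"):
        raise ValueError(f"unknown transition kind {kind!r}")
    rate = _lowpass(rec.gyro("chest", "y"), cutoff_hz)[phase.start : phase.end]
    angle = integrate_pitch(rec, phase)
    out = {
        "duration": phase.duration,
        "max_sagittal_angular_velocity": float(np.abs(rate).max()),
        "trunk_rom": float(angle.max() - angle.min()),
        "max_flexion_angle": float(-angle.min()),
    }
    if kind == "stand_to_sit":
        out["min_lean_angle"] = float(angle.max())
    return out


def arm_swing_excursions(
    rec: SensorRecording,
    walks: Sequence[PhaseInterval],
    side: str,
    cutoff_hz: float = 3.0,
    min_prominence_deg: float = 2.0,
) -> np.ndarray:
    """Per-swing excursions (deg) of one arm across the walk phases.

    The wrist sagittal gyro is low-pass filtered and integrated per walk
    (drift anchored at the phase endpoints); successive angle extrema give
    one excursion per half-stride swing.
    """
    rate = _lowpass(rec.gyro(f"{side}_wrist", "y"), cutoff_hz)
    excursions: list[float] = []
    for walk in walks:
        angle = np.cumsum(rate[walk.start : walk.end]) / FS
        if angle.size < 2:
            continue
        angle = angle - np.linspace(0.0, angle[-1], angle.size)
        peaks, _ = signal.find_peaks(angle, prominence=min_prominence_deg)
        troughs, _ = signal.find_peaks(-angle, prominence=min_prominence_deg)
        extrema = np.sort(np.concatenate([peaks, troughs]))
        if extrema.size >= 2:
            excursions.extend(np.abs(np.diff(angle[extrema])).tolist())
    return np.asarray(excursions)


@dataclasses.dataclass
class FeatureVector:
    """Ordered feature_name → value with per-feature component tags."""

    values: dict[str, float]
    components: dict[str, str]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


@dataclasses.dataclass
class _Context:
    """Everything extractors may need, computed once per subject."""

    rec: SensorRecording
    seg: TUGSegments
    cycles: dict[str, list[GaitCycle]]  # leg -> cycles over both walks
    arm_excursions: dict[str, np.ndarray]  # side -> per-swing excursions
    turns: list[dict[str, float]]
    s2s: dict[str, float]
    sts: dict[str, float]


def _build_context(rec: SensorRecording, seg: TUGSegments) -> _Context:
    walks = seg.component("straight_walk")
    cycles: dict[str, list[GaitCycle]] = {"left": [], "right": []}
    for walk in walks:
        for cyc in detect_gait_cycles(rec, walk):
            cycles[cyc.leg].append(cyc)
    arm = {side: arm_swing_excursions(rec, walks, side) for side in ("left", "right")}
    turns = [turn_kinematics(rec, t) for t in seg.component("turning")]
    s2s = transition_kinematics(rec, seg["sit_to_stand"], "sit_to_stand")
    sts = transition_kinematics(rec, seg["stand_to_sit"], "stand_to_sit")
    return _Context(rec, seg, cycles, arm, turns, s2s, sts)


def _per_leg(ctx: _Context, fn: Callable[[list[GaitCycle]], float]) -> dict[str, float]:
    left = ctx.cycles["left"]
    right = ctx.cycles["right"]
    if len(left) < MIN_CYCLES or len(right) < MIN_CYCLES:
        return {"Max": np.nan, "Min": np.nan, "abs": np.nan}
    return resolve_lateral_pairs(fn(left), fn(right))


def _mean_gct(cycles: list[GaitCycle]) -> float:
    return float(np.mean([c.gct for c in cycles]))


def _gct_cv(cycles: list[GaitCycle]) -> float:
    gct = np.array([c.gct for c in cycles])
    return float(gct.std() / gct.mean())


def _swing_fraction(cycles: list[GaitCycle]) -> float:
    return float(np.mean([c.swing_fraction for c in cycles]))


def _shank_peak(ctx: _Context, cycles: list[GaitCycle]) -> float:
    peaks = []
    for c in cycles:
        x = _lowpass(ctx.rec.gyro(f"{c.leg}_shank", "y"), 6.0)
        peaks.append(np.max(x[c.heel_strike : c.next_heel_strike]))
    return float(np.mean(peaks))


def _arm_pair(ctx: _Context, fn: Callable[[np.ndarray, str], float]) -> dict[str, float]:
    left, right = ctx.arm_excursions["left"], ctx.arm_excursions["right"]
    if left.size < MIN_CYCLES or right.size < MIN_CYCLES:
        return {"Max": np.nan, "Min": np.nan, "abs": np.nan}
    return resolve_lateral_pairs(fn(left, "left"), fn(right, "right"))


def _arm_peak_velocity(ctx: _Context, side: str) -> float:
    rate = _lowpass(ctx.rec.gyro(f"{side}_wrist", "y"), 3.0)
    vals = [
        np.abs(rate[w.start : w.end]).max()
        for w in ctx.seg.component("straight_walk")
    ]
    return float(max(vals))


def compute_parameters(rec: SensorRecording, seg: TUGSegments) -> FeatureVector:
    """The implemented per-subject feature catalogue (34 features).

    Features whose inputs are unavailable (e.g. too few detected gait
    cycles) are set to NaN rather than raising.
    """
    ctx = _build_context(rec, seg)
    values: dict[str, float] = {}
    comps: dict[str, str] = {}

    def add(name: str, component: str, value: float) -> None:
        values[name] = float(value)
        comps[name] = component

    # --- standing (sit-to-stand) ---
    add("SitToStand-Duration", "standing", ctx.s2s["duration"])
    add(
        "SitToStand-Trunk-MaxSagittalAngularVelocity",
        "standing",
        ctx.s2s["max_sagittal_angular_velocity"],
    )
    add("SitToStand-Trunk-MaxFlexionAngle", "standing", ctx.s2s["max_flexion_angle"])
    add("SitToStand-Trunk-ROM", "standing", ctx.s2s["trunk_rom"])

    # --- sitting (stand-to-sit) ---
    add("StandToSit-Duration", "sitting", ctx.sts["duration"])
    add("StandToSit-Trunk-MinLeanAngle", "sitting", ctx.sts["min_lean_angle"])
    add(
        "StandToSit-Trunk-MaxSagittalAngularVelocity",
        "sitting",
        ctx.sts["max_sagittal_angular_velocity"],
    )
    add("StandToSit-Trunk-ROM", "sitting", ctx.sts["trunk_rom"])

    # --- turning ---
    durations = [t["duration"] for t in ctx.turns]
    add("Turn180-Duration", "turning", float(np.mean(durations)))
    add(
        "Turn180-MaxAngularVelocity",
        "turning",
        float(max(t["max_angular_velocity"] for t in ctx.turns)),
    )
    add(
        "Turn180-MeanAngularVelocity",
        "turning",
        float(np.mean([t["mean_angular_velocity"] for t in ctx.turns])),
    )
    add("Turn180-DurationAsymmetry", "turning", float(abs(durations[0] - durations[1])))

    # --- straight walk ---
    for stem, pair in (
        ("Walk-GCT", _per_leg(ctx, _mean_gct)),
        ("Walk-GCTCV", _per_leg(ctx, _gct_cv)),
        ("Walk-SwingFraction", _per_leg(ctx, _swing_fraction)),
        ("Walk-ShankPeakAngularVelocity", _per_leg(ctx, lambda c: _shank_peak(ctx, c))),
        ("Walk-ArmSwingROM", _arm_pair(ctx, lambda x, s: float(np.mean(x)))),
        (
            "Walk-ArmPeakAngularVelocity",
            _arm_pair(ctx, lambda x, s: _arm_peak_velocity(ctx, s)),
        ),
    ):
        for suffix in ("Max", "Min", "abs"):
            add(f"{stem}-{suffix}", "straight_walk", pair[suffix])

    left, right = ctx.arm_excursions["left"], ctx.arm_excursions["right"]
    if left.size >= MIN_CYCLES and right.size >= MIN_CYCLES:
        ssi = symbolic_symmetry_index(left, right)
    else:
        ssi = np.nan
    add("Arm-SymbolicSymmetryIndex", "straight_walk", ssi)

    all_cycles = ctx.cycles["left"] + ctx.cycles["right"]
    if len(all_cycles) >= 2 * MIN_CYCLES:
        mean_gct = float(np.mean([c.gct for c in all_cycles]))
        add("Walk-Cadence", "straight_walk", 120.0 / mean_gct)
    else:
        add("Walk-Cadence", "straight_walk", np.nan)
    add(
        "Walk-Duration",
        "straight_walk",
        sum(w.duration for w in ctx.seg.component("straight_walk")),
    )
    pitch_rom = max(
        float(np.ptp(integrate_pitch(rec, w)))
        for w in ctx.seg.component("straight_walk")
    )
    add("Walk-TrunkPitchROM", "straight_walk", pitch_rom)

    return FeatureVector(values=values, components=comps)


HEADLINE_FEATURES = (
    "Arm-SymbolicSymmetryIndex",
    "StandToSit-Trunk-MinLeanAngle",
    "SitToStand-Trunk-MaxSagittalAngularVelocity",
    "Turn180-MaxAngularVelocity",
)


@dataclasses.dataclass
class FeatureTable:
    """Subjects × features with labels, component tags and split flags."""

    data: pd.DataFrame  # index: subject_id
    labels: pd.Series  # "PD" | "ET", aligned to data.index
    components: dict[str, str]
    split: pd.Series | None = None  # "train" | "test"

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise SchemaError("labels must be aligned to the feature rows")
        missing = [c for c in self.data.columns if c not in self.components]
        if missing:
            raise SchemaError(f"features without component tag: {missing}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, split: str) -> "FeatureTable":
        if self.split is None:
            raise SchemaError("table has no split assignment")
        mask = self.split == split
        return FeatureTable(
            data=self.data.loc[mask],
            labels=self.labels.loc[mask],
            components=self.components,
            split=self.split.loc[mask],
        )

    def component_features(self, component: str) -> list[str]:
        return [f for f in self.data.columns if self.components[f] == component]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        if self.split is not None:
            out.insert(1, "split", self.split)
        tag_row = {
            c: self.components.get(c, "") for c in out.columns if c in self.components
        }
        tag = pd.DataFrame([{**{"label": "", "split": ""}, **tag_row}])
        tag.index = ["__component__"]
        pd.concat([tag[out.columns.intersection(tag.columns)], out]).to_csv(
            path, index_label="subject_id"
        )

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        raw = pd.read_csv(path, index_col="subject_id")
        if "__component__" not in raw.index:
            raise SchemaError("feature CSV lacks the __component__ tag row")
        tags = raw.loc["__component__"]
        body = raw.drop(index="__component__")
        labels = body["label"]
        split = body["split"] if "split" in body.columns else None
        feats = body.drop(columns=[c for c in ("label", "split") if c in body.columns])
        feats = feats.astype(float)
        components = {c: str(tags[c]) for c in feats.columns}
        return cls(data=feats, labels=labels, components=components, split=split)

    @classmethod
    def from_subjects(
        cls, rows: Sequence[tuple[str, str, str | None, FeatureVector]]
    ) -> "FeatureTable":
        """rows: (subject_id, label, split-or-None, features)."""
        if not rows:
            raise SchemaError("no subjects")
        index = [r[0] for r in rows]
        data = pd.DataFrame([r[3].values for r in rows], index=index)
        labels = pd.Series([r[1] for r in rows], index=index, name="label")
        splits = [r[2] for r in rows]
        split = (
            pd.Series(splits, index=index, name="split")
            if all(s is not None for s in splits)
            else None
        )
        return cls(
            data=data,
            labels=labels,
            components=dict(rows[0][3].components),
            split=split,
        )
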