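"""Synthetic TUG cohorts with exact kinematic ground truth.

The generator writes a scripted Timed Up and Go trial directly into sensor
space: stand up from a chair, walk 5 m, turn 180°, walk back, turn again,
sit down. Each phase is a smooth parametric template —

* sit-to-stand / stand-to-sit: raised-cosine trunk-pitch trajectories whose
  peak sagittal velocity and peak backward lean are programmed per subject;
* turns: a cosine-ramp trapezoid of waist/chest yaw rate whose integral is
  exactly 180° (plateau peak programmed, duration derived as 300/peak s);
* walking: per-leg shank/foot gyro bursts on a stride grid (stance 60 %,
  swing 40 %) and sinusoidal arm swing whose per-stride amplitude carries a
  shared stride-to-stride fluctuation plus a programmed left/right
  asymmetry ratio;

plus additive Gaussian sensor noise and a sinusoidal wrist tremor. Phase
boundaries, heel strikes and the drawn kinematic values are recorded as
ground truth, so segmentation and feature extraction can be scored against
what the synthesizer actually did.

Two group profiles (PD and ET) encode the clinically expected contrasts:
the PD profile reduces the sit-to-stand peak trunk velocity by 18.9 %, the
turn peak yaw rate by 13.0 %, the stand-to-sit backward lean by 5.38 %, and
increases arm-swing asymmetry (affected side chosen at random) so that the
extracted arm symbolic symmetry index rises by about 16 % at cohort scale.
Absolute baseline values are plausible physiological magnitudes; only the
PD/ET contrasts are anchored to the clinical effect sizes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .errors import InvariantError, ProfileRangeError
from .sensor_io import (
    AXES,
    PLACEMENTS,
    SAMPLING_RATE,
    SensorRecording,
    SensorStream,
    validate_recording,
)

FS = int(SAMPLING_RATE)

PHASE_NAMES = (
    "sit_to_stand",
    "walk_out",
    "turn_180",
    "walk_back",
    "turn_pre_sit",
    "stand_to_sit",
)

#: Grouping of the six phases into the four analysis components.
COMPONENT_PHASES = {
    "standing": ("sit_to_stand",),
    "straight_walk": ("walk_out", "walk_back"),
    "turning": ("turn_180", "turn_pre_sit"),
    "sitting": ("stand_to_sit",),
}

WALK_DISTANCE_M = 5.0
BASE_STRIDE_LENGTH_M = 1.1
STANCE_FRACTION = 0.6  # of the gait cycle; swing is the remainder
TURN_RAMP_FRACTION = 0.4  # cosine ramp on each side of the yaw plateau
WALK_TAPER_S = 0.15  # envelope ramp at walk-phase boundaries
LEAD_S = 1.0  # motionless sitting before the trial
TAIL_S = 1.0  # motionless sitting after the trial


class Param(NamedTuple):
    """Population mean and between-subject SD of one kinematic."""

    mean: float
    sd: float


@dataclasses.dataclass
class GroupProfile:
    """Programmable kinematics of one diagnostic group."""

    group: str  # "PD" | "ET"
    stride_time: Param = Param(1.08, 0.07)  # s
    stride_length_scale: Param = Param(1.0, 0.08)  # unitless
    arm_swing_amplitude: Param = Param(35.0, 4.0)  # deg, unaffected side
    arm_asymmetry_factor: Param = Param(1.15, 0.015)  # >=1, larger/smaller side
    arm_cycle_variability: Param = Param(0.09, 0.01)  # shared stride-to-stride CV
    turn_peak_angular_velocity: Param = Param(205.0, 22.0)  # deg/s
    turn_duration: Param = Param(300.0 / 205.0, 0.16)  # s (derived: 300/peak)
    sit_to_stand_peak_trunk_pitch_velocity: Param = Param(112.0, 16.0)  # deg/s
    sit_to_stand_duration: Param = Param(1.1, 0.08)  # s
    stand_to_sit_min_lean_angle: Param = Param(8.0, 0.55)  # deg, backward positive
    stand_to_sit_duration: Param = Param(1.6, 0.12)  # s
    tremor_amplitude: Param = Param(20.0, 8.0)  # deg/s, wrist roll axis
    tremor_frequency: Param = Param(7.0, 1.0)  # Hz
    noise_sd_gyro: float = 1.0  # deg/s, every gyro channel
    noise_sd_accel: float = 0.02  # g, every accel channel

    def validate(self) -> None:
        for name, param in dataclasses.asdict(self).items():
            if isinstance(param, (tuple, Param)):
                mean, sd = param
                if not np.isfinite(mean):
                    raise InvariantError(f"profile {name}: non-finite mean")
                if sd < 0:
                    raise InvariantError(f"profile {name}: negative SD")
        if self.turn_duration.mean <= 0:
            raise InvariantError("turn_duration must be positive")
        if not (3.0 <= self.tremor_frequency.mean <= 12.0):
            raise InvariantError("tremor_frequency mean must lie in [3, 12] Hz")
        if self.arm_asymmetry_factor.mean < 1.0:
            raise InvariantError("arm_asymmetry_factor must be >= 1")


def default_et_profile() -> GroupProfile:
    """Baseline group: tremor without parkinsonian gait impairment."""
    return GroupProfile(group="ET")


def default_pd_profile() -> GroupProfile:
    """Early-PD group: bradykinetic transitions/turns and asymmetric arm swing.

    Contrast ratios against the ET baseline: sit-to-stand peak trunk pitch
    velocity ×0.811, turn peak yaw rate ×0.870, stand-to-sit backward lean
    ×0.9462; the asymmetry ratio is calibrated so the extracted symbolic
    symmetry index is ≈16 % higher at cohort scale. PD additionally walks
    slower with shorter strides and globally reduced arm swing.
    """
    return GroupProfile(
        group="PD",
        stride_time=Param(1.15, 0.09),
        stride_length_scale=Param(0.85, 0.10),
        arm_swing_amplitude=Param(28.0, 4.5),
        arm_asymmetry_factor=Param(1.191, 0.020),
        turn_peak_angular_velocity=Param(205.0 * 0.870, 24.0),
        turn_duration=Param(300.0 / (205.0 * 0.870), 0.20),
        sit_to_stand_peak_trunk_pitch_velocity=Param(112.0 * 0.811, 16.0),
        stand_to_sit_min_lean_angle=Param(8.0 * 0.9462, 0.60),
        tremor_amplitude=Param(25.0, 10.0),
        tremor_frequency=Param(5.0, 0.5),
    )


@dataclasses.dataclass
class GroundTruth:
    """What the synthesizer actually did: exact boundaries and drawn values."""

    phases: dict[str, tuple[int, int]]  # half-open sample ranges
    heel_strikes: dict[str, list[int]]  # leg -> ascending sample indices
    toe_offs: dict[str, list[int]]  # leg -> one per full cycle
    params: dict[str, float]  # drawn per-subject kinematics
    seed: int

    def component_of_sample(self, n_samples: int) -> np.ndarray:
        """Label every sample with its phase name ('' outside the trial)."""
        out = np.full(n_samples, "", dtype=object)
        for name, (start, end) in self.phases.items():
            out[start:end] = name
        return out


@dataclasses.dataclass
class CohortConfig:
    """Cohort composition mirroring the clinical dataset by default.

    164 recordings (84 PD, 80 ET); the default split reproduces the matched
    training groups (64 PD + 67 ET train, 20 PD + 13 ET test). With
    non-default sizes the split falls back to rounding ``train_fraction``
    per group.
    """

    n_pd: int = 84
    n_et: int = 80
    pd_profile: GroupProfile = dataclasses.field(default_factory=default_pd_profile)
    et_profile: GroupProfile = dataclasses.field(default_factory=default_et_profile)
    seed: int = 0
    train_fraction: float = 0.8
    train_n_pd: int | None = None
    train_n_et: int | None = None

    def validate(self) -> None:
        if self.n_pd < 1 or self.n_et < 1:
            raise InvariantError("n_pd and n_et must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise InvariantError("train_fraction must lie in (0, 1)")
        self.pd_profile.validate()
        self.et_profile.validate()

    def split_counts(self) -> tuple[int, int]:
        """(train_n_pd, train_n_et)."""
        if self.train_n_pd is not None and self.train_n_et is not None:
            return self.train_n_pd, self.train_n_et
        if self.n_pd == 84 and self.n_et == 80 and self.train_fraction == 0.8:
            return 64, 67  # the clinical study's matched training groups
        return (
            int(round(self.train_fraction * self.n_pd)),
            int(round(self.train_fraction * self.n_et)),
        )


@dataclasses.dataclass
class CohortSubject:
    recording: SensorRecording
    truth: GroundTruth
    label: str
    split: str  # "train" | "test"


@dataclasses.dataclass
class CohortDataset:
    subjects: list[CohortSubject]
    config: CohortConfig

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


def _draw(rng: np.random.Generator, param: Param, low: float | None = None) -> float:
    value = rng.normal(param.mean, param.sd)
    # keep draws physiological: clamp at 3 SD and an optional hard floor
    value = float(np.clip(value, param.mean - 3 * param.sd, param.mean + 3 * param.sd))
    if low is not None:
        value = max(value, low)
    return value


def _cos_ramp(n: int) -> np.ndarray:
    """Half raised-cosine from 0 to 1 over n samples."""
    return 0.5 * (1.0 - np.cos(np.pi * np.arange(n) / max(n, 1)))


def generate_subject(
    profile: GroupProfile,
    seed: int,
    subject_id: str = "S0000",
    label: str | None = None,
) -> tuple[SensorRecording, GroundTruth]:
    """Synthesize one labeled TUG recording with exact ground truth.

    Deterministic: the same (profile, seed) pair always yields identical
    output. Raises :class:`ProfileRangeError` if the programmed kinematics
    exceed the ±2000 deg/s gyroscope range before noise.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    label = label if label is not None else profile.group

    # --- per-subject kinematic draws -------------------------------------
    stride_time = _draw(rng, profile.stride_time, low=0.7)
    stride_scale = _draw(rng, profile.stride_length_scale, low=0.4)
    arm_amp = _draw(rng, profile.arm_swing_amplitude, low=5.0)
    asym = max(1.0, _draw(rng, profile.arm_asymmetry_factor))
    cycle_cv = max(0.0, _draw(rng, profile.arm_cycle_variability))
    affected_right = bool(rng.integers(0, 2))
    turn_peak_1 = _draw(rng, profile.turn_peak_angular_velocity, low=40.0)
    turn_peak_2 = turn_peak_1 * float(np.clip(rng.normal(1.0, 0.03), 0.9, 1.1))
    s2s_peak = _draw(rng, profile.sit_to_stand_peak_trunk_pitch_velocity, low=30.0)
    s2s_dur = _draw(rng, profile.sit_to_stand_duration, low=0.6)
    sts_lean = _draw(rng, profile.stand_to_sit_min_lean_angle, low=1.0)
    sts_dur = _draw(rng, profile.stand_to_sit_duration, low=0.9)
    sts_flexion = _draw(rng, Param(25.0, 2.0), low=10.0)
    tremor_amp = max(0.0, _draw(rng, profile.tremor_amplitude))
    tremor_freq = float(np.clip(_draw(rng, profile.tremor_frequency), 3.0, 12.0))

    stride_len = BASE_STRIDE_LENGTH_M * stride_scale
    n_strides = max(5, int(round(WALK_DISTANCE_M / stride_len)))

    # --- phase durations in samples --------------------------------------
    lead = int(round(LEAD_S * FS))
    n_s2s = int(round(s2s_dur * FS))
    n_walk = int(round(n_strides * stride_time * FS))
    turn_dur_1 = 300.0 / turn_peak_1  # 180 deg = peak * 0.6 * duration
    turn_dur_2 = 300.0 / turn_peak_2
    n_turn_1 = int(round(turn_dur_1 * FS))
    n_turn_2 = int(round(turn_dur_2 * FS))
    n_sts = int(round(sts_dur * FS))
    tail = int(round(TAIL_S * FS))

    bounds = np.cumsum([lead, n_s2s, n_walk, n_turn_1, n_walk, n_turn_2, n_sts])
    n_total = int(bounds[-1] + tail)
    phases = {
        name: (int(bounds[i]), int(bounds[i + 1])) for i, name in enumerate(PHASE_NAMES)
    }

    t = np.arange(n_total) / FS
    pitch_rate = np.zeros(n_total)  # trunk, deg/s, backward positive
    yaw_rate = np.zeros(n_total)  # trunk, deg/s
    shank = {"left": np.zeros(n_total), "right": np.zeros(n_total)}
    wrist = {"left": np.zeros(n_total), "right": np.zeros(n_total)}

    # --- sit-to-stand: one full sine period of pitch rate -----------------
    s0, s1 = phases["sit_to_stand"]
    tau = (np.arange(s1 - s0)) / (s1 - s0)  # 0..1
    pitch_rate[s0:s1] = -s2s_peak * np.sin(2 * np.pi * tau)

    # --- walking phases ----------------------------------------------------
    heel_strikes = {"left": [], "right": []}
    toe_offs = {"left": [], "right": []}
    # shared stride-to-stride amplitude fluctuation (both arms, both walks)
    c_fluct = np.clip(rng.normal(1.0, cycle_cv, size=2 * n_strides + 2), 0.3, None)
    # the *affected* side is the reduced one; `asym` is the big/small ratio
    amp_big, amp_small = arm_amp, arm_amp / asym
    if affected_right:
        arm_base = {"left": amp_big, "right": amp_small}
    else:
        arm_base = {"left": amp_small, "right": amp_big}

    swing_peak = 320.0 * (0.9 + 0.2 * stride_scale)  # shank mid-swing, deg/s
    stance_amp = 32.0

    for w_idx, walk_name in enumerate(("walk_out", "walk_back")):
        w0, w1 = phases[walk_name]
        n_w = w1 - w0
        tw = np.arange(n_w) / FS
        omega = 2 * np.pi / stride_time

        env = np.ones(n_w)
        n_taper = int(WALK_TAPER_S * FS)
        env[:n_taper] = _cos_ramp(n_taper)
        env[n_w - n_taper :] = _cos_ramp(n_taper)[::-1]

        for leg, leg_offset in (("left", 0.0), ("right", 0.5)):
            # cycle-phase in [0,1) for this leg; heel strike at phase 0
            phase = (tw / stride_time - leg_offset) % 1.0
            burst = np.zeros(n_w)
            in_swing = phase >= STANCE_FRACTION
            sw = (phase[in_swing] - STANCE_FRACTION) / (1 - STANCE_FRACTION)
            burst[in_swing] = swing_peak * np.sin(np.pi * sw) ** 2
            st = phase[~in_swing] / STANCE_FRACTION
            burst[~in_swing] = -stance_amp * np.sin(np.pi * st) ** 2
            shank[leg][w0:w1] += burst * env

            # ground-truth gait events for this walk
            k = leg_offset
            while True:
                hs = w0 + int(round(k * stride_time * FS))
                if hs > w1:
                    break
                heel_strikes[leg].append(hs)
                to = w0 + int(round((k + STANCE_FRACTION) * stride_time * FS))
                if to <= w1:
                    toe_offs[leg].append(to)
                k += 1.0

        # arm swing: contralateral to the ipsilateral leg (left arm with
        # right leg); amplitude per stride = shared fluctuation x side base
        stride_idx = np.minimum(
            (tw / stride_time).astype(int) + w_idx * n_strides, len(c_fluct) - 1
        )
        amp_t = c_fluct[stride_idx]
        for side, phi in (("left", np.pi), ("right", 0.0)):
            amp = arm_base[side] * amp_t
            wrist[side][w0:w1] += (
                0.5 * amp * omega * np.cos(omega * tw + phi) * env
            )

        # small trunk oscillations while walking (below detection thresholds)
        pitch_rate[w0:w1] += 6.0 * np.sin(2 * omega * tw) * env
        yaw_rate[w0:w1] += 3.0 * np.sin(omega * tw + 1.3) * env

    # --- turns: cosine-ramp trapezoid integrating to exactly 180 deg ------
    for turn_name, peak in (("turn_180", turn_peak_1), ("turn_pre_sit", turn_peak_2)):
        u0, u1 = phases[turn_name]
        n_u = u1 - u0
        n_ramp = int(round(TURN_RAMP_FRACTION * n_u))
        pulse = np.full(n_u, peak)
        pulse[:n_ramp] = peak * _cos_ramp(n_ramp)
        pulse[n_u - n_ramp :] = peak * _cos_ramp(n_ramp)[::-1]
        # renormalize the discrete pulse so the sampled integral is 180 deg
        pulse *= 180.0 / (np.sum(pulse) / FS)
        yaw_rate[u0:u1] += pulse

    # --- stand-to-sit: flexion dip then programmed backward peak ----------
    # The pitch-angle trajectory is laid down on the sample grid and
    # differentiated, so integrating the gyro stream recovers the programmed
    # backward peak (sts_lean) exactly: forward flexion to -sts_flexion,
    # backward overshoot to +sts_lean, return to upright.
    d0, d1 = phases["stand_to_sit"]
    n_d = d1 - d0
    n_a = int(round(0.45 * n_d))
    n_b = int(round(0.30 * n_d))
    n_c = n_d - n_a - n_b
    theta_seg = np.zeros(n_d + 1)
    i = np.arange(n_a + 1)
    theta_seg[: n_a + 1] = -sts_flexion * np.sin(np.pi * i / (2 * n_a)) ** 2
    i = np.arange(n_b + 1)
    theta_seg[n_a : n_a + n_b + 1] = (
        -sts_flexion + (sts_flexion + sts_lean) * np.sin(np.pi * i / (2 * n_b)) ** 2
    )
    i = np.arange(n_c + 1)
    theta_seg[n_a + n_b :] = sts_lean * np.cos(np.pi * i / (2 * n_c)) ** 2
    pitch_rate[d0:d1] = np.diff(theta_seg) * FS

    # --- range check before noise -----------------------------------------
    for name, arr in (
        ("trunk pitch", pitch_rate),
        ("trunk yaw", yaw_rate),
        ("shank left", shank["left"]),
        ("shank right", shank["right"]),
        ("wrist left", wrist["left"]),
        ("wrist right", wrist["right"]),
    ):
        if np.max(np.abs(arr)) + tremor_amp > 1999.0:
            raise ProfileRangeError(
                f"{name} reaches {np.max(np.abs(arr)):.0f} deg/s; exceeds sensor range"
            )

    # --- assemble sensor streams ------------------------------------------
    pitch_angle = np.cumsum(pitch_rate) / FS  # deg, backward positive
    g_noise = profile.noise_sd_gyro
    a_noise = profile.noise_sd_accel

    def noisy(base: np.ndarray, sd: float) -> np.ndarray:
        return base + rng.normal(0.0, sd, size=n_total) if sd > 0 else base.copy()

    step_bounce = np.zeros(n_total)
    for walk_name in ("walk_out", "walk_back"):
        w0, w1 = phases[walk_name]
        tw = np.arange(w1 - w0) / FS
        step_bounce[w0:w1] = 0.05 * np.sin(2 * np.pi * 2 * tw / stride_time)

    tremor = {"left": np.zeros(n_total), "right": np.zeros(n_total)}
    tremor_wave = np.sin(2 * np.pi * tremor_freq * t + rng.uniform(0, 2 * np.pi))
    if profile.group == "PD":
        big, small = tremor_amp, 0.3 * tremor_amp
        tremor["right" if affected_right else "left"] = big * tremor_wave
        tremor["left" if affected_right else "right"] = small * tremor_wave
    else:
        tremor["left"] = tremor_amp * tremor_wave
        tremor["right"] = 0.8 * tremor_amp * tremor_wave

    theta = np.deg2rad(pitch_angle)
    sensors: dict[str, SensorStream] = {}
    for placement in PLACEMENTS:
        gx = np.zeros(n_total)
        gy = np.zeros(n_total)
        gz = np.zeros(n_total)
        ax = np.zeros(n_total)
        ay = np.zeros(n_total)
        az = np.ones(n_total)

        if placement in ("chest", "waist"):
            gy = pitch_rate
            gz = yaw_rate
            ax = -np.sin(theta)
            az = np.cos(theta)
        elif placement.endswith("wrist"):
            side = placement.split("_")[0]
            gy = wrist[side]
            gx = tremor[side]
            az = 1.0 + step_bounce
        elif placement.endswith("shank"):
            side = placement.split("_")[0]
            gy = shank[side]
            az = 1.0 + step_bounce
        elif placement.endswith("foot"):
            side = placement.split("_")[0]
            gy = 1.1 * shank[side]
            az = 1.0 + step_bounce
        elif placement.endswith("thigh"):
            side = placement.split("_")[0]
            gy = 0.5 * shank[side]
            az = 1.0 + step_bounce

        accel = np.vstack(
            [noisy(ax, a_noise), noisy(ay, a_noise), noisy(az, a_noise)]
        )
        gyro = np.vstack([noisy(gx, g_noise), noisy(gy, g_noise), noisy(gz, g_noise)])
        sensors[placement] = SensorStream(accel=accel, gyro=gyro)

    rec = SensorRecording(subject_id=subject_id, label=label, sensors=sensors)

    truth = GroundTruth(
        phases=phases,
        heel_strikes={leg: sorted(v) for leg, v in heel_strikes.items()},
        toe_offs={leg: sorted(v) for leg, v in toe_offs.items()},
        params={
            "stride_time": stride_time,
            "stride_length_scale": stride_scale,
            "n_strides_per_walk": float(n_strides),
            "arm_swing_amplitude": arm_amp,
            "arm_asymmetry_factor": asym,
            "affected_side": float(affected_right),  # 1 = right
            "turn_peak_angular_velocity_1": turn_peak_1,
            "turn_peak_angular_velocity_2": turn_peak_2,
            "sit_to_stand_peak_trunk_pitch_velocity": s2s_peak,
            "sit_to_stand_duration": s2s_dur,
            "stand_to_sit_min_lean_angle": sts_lean,
            "stand_to_sit_duration": sts_dur,
            "tremor_amplitude": tremor_amp,
            "tremor_frequency": tremor_freq,
        },
        seed=int(seed),
    )
    return rec, truth


def subject_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-subject seeds derived from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)


def cohort_manifest(config: CohortConfig) -> list[tuple[str, str, str, int]]:
    """(subject_id, label, split, seed) for every cohort member.

    Deterministic from the master seed; computable without synthesizing any
    signal. Subject order: all PD first, then all ET.
    """
    config.validate()
    n_total = config.n_pd + config.n_et
    seeds = subject_seeds(config.seed, n_total)
    split_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA11CE)))
    train_pd, train_et = config.split_counts()
    pd_train_idx = set(split_rng.choice(config.n_pd, size=train_pd, replace=False))
    et_train_idx = set(split_rng.choice(config.n_et, size=train_et, replace=False))

    rows = []
    k = 0
    for group, n_group, train_idx in (
        ("PD", config.n_pd, pd_train_idx),
        ("ET", config.n_et, et_train_idx),
    ):
        for i in range(n_group):
            split = "train" if i in train_idx else "test"
            rows.append((f"{group}{i:04d}", group, split, int(seeds[k])))
            k += 1
    return rows


def iter_cohort(config: CohortConfig) -> Iterator[CohortSubject]:
    """Stream cohort subjects one at a time (memory-friendly)."""
    profile_of = {"PD": config.pd_profile, "ET": config.et_profile}
    for sid, label, split, seed in cohort_manifest(config):
        rec, truth = generate_subject(
            profile_of[label], seed, subject_id=sid, label=label
        )
        yield CohortSubject(recording=rec, truth=truth, label=label, split=split)


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Materialize the full cohort as a list (see :func:`iter_cohort`)."""
    return CohortDataset(subjects=list(iter_cohort(config)), config=config)


def write_cohort(dataset: CohortDataset, outdir: str | Path) -> Path:
    """Write recordings, per-subject ground truth and a manifest CSV."""
    from .sensor_io import write_recording  # local import to avoid cycle at init

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in dataset:
        rec_path = outdir / f"{subj.recording.subject_id}.csv"
        write_recording(subj.recording, rec_path)
        gt_path = outdir / f"{subj.recording.subject_id}.truth.json"
        with open(gt_path, "w") as fh:
            json.dump(
                {
                    "phases": {k: list(v) for k, v in subj.truth.phases.items()},
                    "heel_strikes": subj.truth.heel_strikes,
                    "toe_offs": subj.truth.toe_offs,
                    "params": subj.truth.params,
                    "seed": subj.truth.seed,
                },
                fh,
                indent=1,
            )
        rows.append(
            {
                "subject_id": subj.recording.subject_id,
                "label": subj.label,
                "split": subj.split,
                "seed": subj.truth.seed,
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir


def _self_check(rec: SensorRecording) -> None:
    report = validate_recording(rec)
    if not report.ok:  # pragma: no cover - generator bug guard
        raise InvariantError("; ".join(i.message for i in report.issues))
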