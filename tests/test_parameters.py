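"""Feature extraction: lateral pairs, symmetry index, turn/transition kinematics."""

import numpy as np
import pytest

from tugait.errors import InsufficientCyclesError
from tugait.parameters import (
    compute_parameters,
    resolve_lateral_pairs,
    symbolic_symmetry_index,
    transition_kinematics,
    turn_kinematics,
)
from tugait.segmentation import PhaseInterval, TUGSegments, segment_tug
from tugait.synthetic import generate_subject

from conftest import fixed, quiet_recording, zero_noise


@pytest.mark.parametrize(
    "left,right,expected",
    [
        (3.0, 5.0, {"Max": 5.0, "Min": 3.0, "abs": 2.0}),
        (4.2, 4.2, {"Max": 4.2, "Min": 4.2, "abs": 0.0}),
        (-1.0, 2.0, {"Max": 2.0, "Min": -1.0, "abs": 3.0}),
    ],
)
def test_resolve_lateral_pairs(left, right, expected):
    assert resolve_lateral_pairs(left, right) == expected


def test_resolve_lateral_pairs_rejects_non_finite():
    with pytest.raises(ValueError):
        resolve_lateral_pairs(float("nan"), 1.0)


def tv_distance_oracle(left, right, n_bins=8):
    """Independent brute-force symbolization: explicit per-value loops."""
    left = [round(v, 9) for v in left]
    right = [round(v, 9) for v in right]
    lo, hi = min(left + right), max(left + right)
    if hi == lo:
        return 0.0
    width = (hi - lo) / n_bins

    def symbol(v):
        k = int((v - lo) / width)
        return min(k, n_bins - 1)

    counts_l = [0] * n_bins
    counts_r = [0] * n_bins
    for v in left:
        counts_l[symbol(v)] += 1
    for v in right:
        counts_r[symbol(v)] += 1
    return 0.5 * sum(
        abs(a / len(left) - b / len(right)) for a, b in zip(counts_l, counts_r)
    )


def test_symmetry_index_identical_series_is_zero():
    series = [30.0, 31.5, 29.0, 30.5, 32.0]
    assert symbolic_symmetry_index(series, series) == 0.0


def test_symmetry_index_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        left = rng.normal(30.0, 3.0, size=rng.integers(5, 15)).tolist()
        right = (2.0 * np.asarray(rng.choice(left, size=len(left)))).tolist()
        got = symbolic_symmetry_index(left, right)
        assert got == pytest.approx(tv_distance_oracle(left, right), abs=1e-12)
        assert 0.0 <= got <= 1.0


def test_symmetry_index_requires_three_cycles():
    with pytest.raises(InsufficientCyclesError):
        symbolic_symmetry_index([1.0, 2.0], [1.0, 2.0, 3.0])


def test_symmetry_index_monotone_in_programmed_asymmetry(et_profile):
    values = []
    for asym in (1.0, 1.1, 1.2, 1.3):
        prof = fixed(zero_noise(et_profile), arm_asymmetry_factor=asym)
        rec, _ = generate_subject(prof, 3)
        fv = compute_parameters(rec, segment_tug(rec))
        values.append(fv.values["Arm-SymbolicSymmetryIndex"])
    assert values[0] == pytest.approx(0.0, abs=1e-9)
    assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
    assert values[-1] > values[0]


def test_turn_kinematics_constant_plateau():
    rec = quiet_recording(600)
    rec.sensors["waist"].gyro[2, 195:405] = 90.0
    out = turn_kinematics(rec, PhaseInterval("turn", 200, 400))
    assert out["duration"] == pytest.approx(2.0)
    assert out["mean_angular_velocity"] == pytest.approx(90.0, abs=1.0)
    assert out["max_angular_velocity"] == pytest.approx(90.0, abs=1.0)


def test_turn_kinematics_bell_peak():
    rec = quiet_recording(600)
    t = np.arange(180) / 100.0
    rec.sensors["waist"].gyro[2, 200:380] = 180.0 * np.sin(np.pi * t / 1.8) ** 2
    out = turn_kinematics(rec, PhaseInterval("turn", 200, 380))
    assert out["max_angular_velocity"] == pytest.approx(180.0, abs=2.0)
    assert out["mean_angular_velocity"] <= out["max_angular_velocity"]


def test_programmed_kinematics_recovered(et_profile):
    prof = fixed(
        zero_noise(et_profile),
        turn_peak_angular_velocity=200.0,
        sit_to_stand_peak_trunk_pitch_velocity=120.0,
        stand_to_sit_min_lean_angle=8.0,
    )
    rec, _ = generate_subject(prof, 21)
    seg = segment_tug(rec)
    fv = compute_parameters(rec, seg).values
    assert fv["Turn180-MaxAngularVelocity"] == pytest.approx(200.0, abs=5.0)
    assert fv["SitToStand-Trunk-MaxSagittalAngularVelocity"] == pytest.approx(
        120.0, abs=3.0
    )
    assert fv["StandToSit-Trunk-MinLeanAngle"] == pytest.approx(8.0, abs=1.0)


def test_transition_kinematics_sign_convention(noisefree_et_subject):
    rec, gt = noisefree_et_subject
    s, e = gt.phases["stand_to_sit"]
    out = transition_kinematics(rec, PhaseInterval("sts", s, e), "stand_to_sit")
    # backward lean positive, and the forward flexion dip is larger
    assert out["min_lean_angle"] > 0
    assert out["max_flexion_angle"] > out["min_lean_angle"]


def test_zero_noise_symmetric_subject_has_null_lateral_features(et_profile):
    prof = fixed(zero_noise(et_profile), arm_asymmetry_factor=1.0)
    rec, _ = generate_subject(prof, 17)
    fv = compute_parameters(rec, segment_tug(rec)).values
    assert fv["Arm-SymbolicSymmetryIndex"] == pytest.approx(0.0, abs=1e-9)
    assert fv["Walk-ArmSwingROM-abs"] == pytest.approx(0.0, abs=1e-6)
    assert fv["Walk-GCT-abs"] <= 0.02


def test_feature_catalogue_shape_and_positivity(noisy_et_subject):
    rec, _ = noisy_et_subject
    fv = compute_parameters(rec, segment_tug(rec))
    assert len(fv.values) >= 30
    assert set(fv.components.values()) == {
        "standing",
        "straight_walk",
        "turning",
        "sitting",
    }
    for name, value in fv.values.items():
        if "Velocity" in name or name.endswith("-abs"):
            assert value >= 0.0, name
        if "Duration" in name and "Asymmetry" not in name:
            assert value > 0.0, name


def test_absent_cycles_flagged_as_nan(noisy_et_subject):
    rec, gt = noisy_et_subject
    seg = segment_tug(rec)
    # shrink the walk phases below one stride so cycle detection fails
    phases = dict(seg.phases)
    for walk in ("walk_out", "walk_back"):
        p = phases[walk]
        phases[walk] = PhaseInterval(walk, p.start, p.start + 40)
    crippled = TUGSegments(phases=phases)
    fv = compute_parameters(rec, crippled).values
    assert np.isnan(fv["Walk-GCT-Max"])
    assert np.isnan(fv["Arm-SymbolicSymmetryIndex"])
    # non-walk features remain available
    assert np.isfinite(fv["Turn180-MaxAngularVelocity"])
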