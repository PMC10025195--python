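"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd
import pytest

from tugait.parameters import FeatureTable
from tugait.sensor_io import PLACEMENTS, SensorRecording, SensorStream
from tugait.synthetic import (
    GroupProfile,
    Param,
    default_et_profile,
    default_pd_profile,
    generate_subject,
)


def zero_noise(profile: GroupProfile) -> GroupProfile:
    """Copy of a profile with sensor noise and tremor switched off."""
    prof = copy.deepcopy(profile)
    prof.noise_sd_gyro = 0.0
    prof.noise_sd_accel = 0.0
    prof.tremor_amplitude = Param(0.0, 0.0)
    return prof


def fixed(profile: GroupProfile, **overrides: float) -> GroupProfile:
    """Copy of a profile with chosen kinematics pinned (SD = 0)."""
    prof = copy.deepcopy(profile)
    for name, mean in overrides.items():
        setattr(prof, name, Param(mean, 0.0))
    return prof


def quiet_recording(n_samples: int, subject_id: str = "quiet") -> SensorRecording:
    """A motionless recording: unit gravity on z, zero rotation."""
    sensors = {}
    for placement in PLACEMENTS:
        accel = np.zeros((3, n_samples))
        accel[2] = 1.0
        sensors[placement] = SensorStream(accel=accel, gyro=np.zeros((3, n_samples)))
    return SensorRecording(subject_id=subject_id, label="UNKNOWN", sensors=sensors)


def gaussian_feature_table(
    n_per_class: int,
    effects: dict[str, tuple[str, float]],
    seed: int = 0,
) -> FeatureTable:
    """Synthetic subjects × features table sampled at the feature level.

    ``effects`` maps feature name -> (component, group-mean shift in SD
    units applied to PD). Used where tests need controlled feature
    statistics without synthesizing raw signals.
    """
    rng = np.random.default_rng(seed)
    ids = [f"PD{i:03d}" for i in range(n_per_class)] + [
        f"ET{i:03d}" for i in range(n_per_class)
    ]
    labels = pd.Series(["PD"] * n_per_class + ["ET"] * n_per_class, index=ids)
    data = {}
    components = {}
    for name, (component, shift) in effects.items():
        x = rng.normal(0.0, 1.0, size=2 * n_per_class)
        x[:n_per_class] += shift
        data[name] = x
        components[name] = component
    return FeatureTable(
        data=pd.DataFrame(data, index=ids), labels=labels, components=components
    )


@pytest.fixture(scope="session")
def et_profile() -> GroupProfile:
    return default_et_profile()


@pytest.fixture(scope="session")
def pd_profile() -> GroupProfile:
    return default_pd_profile()


@pytest.fixture(scope="session")
def noisefree_et_subject():
    """One deterministic, noise-free ET subject with ground truth."""
    return generate_subject(zero_noise(default_et_profile()), 42, subject_id="ET-free")


@pytest.fixture(scope="session")
def noisy_et_subject():
    """One deterministic default-noise ET subject with ground truth."""
    return generate_subject(default_et_profile(), 42, subject_id="ET-noisy")
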