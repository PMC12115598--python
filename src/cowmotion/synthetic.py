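"""Synthetic five-behavior collar-IMU databases.

Generates labeled events with the statistical structure the analysis
assumes, so the whole pipeline is testable without the real herd data.
Each behavior has a phenomenological signal model built from sinusoids,
random bursts and envelopes:

* active mounting — two high-energy oscillation peaks (the climb and the
  dismount) straddling a quiet middle phase;
* walking — rhythmic ~1.5 Hz oscillation, strongest on the horizontal axes;
* head nodding — ~1.5 Hz oscillation on the vertical axis;
* grazing — irregular short vigorous bursts (Poisson arrivals);
* resting — near-silence around gravity.

Behavior motion is defined in the WORLD frame and mapped into the body
frame through an arbitrary, slowly wobbling collar orientation, so
body-frame signals are orientation-confounded while world-frame signals
are not — the premise the frame comparison tests. Stored world-frame
channels are exactly R(q) applied to the body-frame channels; the
accelerometer keeps gravity (specific force).

Event durations follow the field recordings: mounts ~9 s, walks ~14 s,
rests ~20 s, nods ~8 s, grazing ~71 s, never below 7 s.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io_dataset import (BEHAVIORS, NUMERIC_COLUMNS, SAMPLE_RATE_HZ,
                         EventRecording, write_event_csv)
from .preprocessing import (GRAVITY, SensorSpec, accel_to_raw, gyro_to_raw,
                            normalize_quaternion, quat_multiply,
                            quat_to_rotation)

#: world-frame magnetic field used to fill magnetometer channels (schema
#: completeness only; no feature reads them)
MAGNETIC_FIELD = np.array([22.0, 5.0, -43.0])


@dataclass(frozen=True)
class BehaviorProfile:
    """Parameters of one behavior's signal model (world-frame motion)."""

    name: str
    duration_mean_s: float
    duration_sd_s: float
    duration_min_s: float = 7.0
    osc_freq_hz: float = 0.0
    osc_amp: tuple = (0.0, 0.0, 0.0)   # m/s^2 per world axis
    burst_rate_hz: float = 0.0
    burst_amp: float = 0.0             # m/s^2
    peak_amp: float = 0.0              # mount start/end peaks, m/s^2
    peak_len_s: float = 1.0
    peak_freq_hz: float = 4.0
    noise_sd: float = 0.1              # m/s^2, body-frame sensor noise
    gyro_scale_dps: float = 5.0

    def __post_init__(self):
        if self.duration_min_s < 7.0:
            raise ValueError("events must be at least 7 s (one window)")
        if min(self.osc_amp) < 0 or self.noise_sd < 0 or self.peak_amp < 0:
            raise ValueError("amplitudes and noise sd must be >= 0")


DEFAULT_PROFILES = {
    "active_mounting": BehaviorProfile(
        name="active_mounting", duration_mean_s=9, duration_sd_s=1.5,
        peak_amp=8.0, peak_len_s=1.0, peak_freq_hz=4.0,
        noise_sd=0.2, gyro_scale_dps=60.0),
    "walking": BehaviorProfile(
        name="walking", duration_mean_s=14, duration_sd_s=3,
        osc_freq_hz=1.5, osc_amp=(2.0, 2.0, 0.3),
        noise_sd=0.3, gyro_scale_dps=30.0),
    "resting": BehaviorProfile(
        name="resting", duration_mean_s=20, duration_sd_s=5,
        noise_sd=0.05, gyro_scale_dps=1.0),
    "grazing": BehaviorProfile(
        name="grazing", duration_mean_s=71, duration_sd_s=15,
        duration_min_s=10.0, burst_rate_hz=1.5, burst_amp=4.0,
        noise_sd=0.3, gyro_scale_dps=50.0),
    "head_nodding": BehaviorProfile(
        name="head_nodding", duration_mean_s=8, duration_sd_s=1,
        osc_freq_hz=1.5, osc_amp=(0.3, 0.3, 3.0),
        noise_sd=0.3, gyro_scale_dps=40.0),
}

#: field-study class composition (number of labeled events per behavior)
STUDY_COUNTS = {"active_mounting": 21, "walking": 186, "resting": 83,
                "head_nodding": 43, "grazing": 82}


def interpolate_profiles(a: BehaviorProfile, b: BehaviorProfile,
                         t: float) -> BehaviorProfile:
    """Linear interpolation of two profiles' numeric parameters.

    ``t=0`` gives ``a``, ``t=1`` gives ``b``; used to degrade the mount
    signature toward the nodding signature.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must be in [0, 1]")
    kw = {}
    for f in dataclasses.fields(BehaviorProfile):
        va, vb = getattr(a, f.name), getattr(b, f.name)
        if f.name == "name":
            kw[f.name] = a.name  # a degraded mount is still a mount
        elif isinstance(va, tuple):
            kw[f.name] = tuple((1 - t) * x + t * y for x, y in zip(va, vb))
        else:
            kw[f.name] = (1 - t) * va + t * vb
    return BehaviorProfile(**kw)


def random_unit_quaternion(rng) -> np.ndarray:
    """Uniformly random rotation, scalar-first."""
    q = rng.standard_normal(4)
    return normalize_quaternion(q)


def axis_angle_quaternion(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = angle_rad / 2
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def make_orientation_trace(n: int, base=None, wobble_deg_s: float = 2.0,
                           seed: int = 0, fs: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """(n, 4) slowly varying unit-quaternion trace around ``base``.

    Random-walk: each sample rotates the previous orientation by
    ``wobble_deg_s / fs`` degrees about a random axis, emulating collar
    sway on the neck. ``wobble=0`` gives a constant trace.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if wobble_deg_s < 0:
        raise ValueError("wobble must be >= 0")
    rng = np.random.default_rng(seed)
    if base is None:
        base = random_unit_quaternion(rng)
    q = normalize_quaternion(base)
    out = np.empty((n, 4))
    out[0] = q
    step_rad = np.deg2rad(wobble_deg_s) / fs
    for i in range(1, n):
        if step_rad > 0:
            axis = rng.standard_normal(3)
            dq = axis_angle_quaternion(axis, step_rad)
            q = normalize_quaternion(quat_multiply(q, dq))
        out[i] = q
    return out


def _smoothed_noise(rng, n: int, width: int = 5) -> np.ndarray:
    """Band-limited unit-scale noise (moving-average of white noise)."""
    w = rng.standard_normal(n + width - 1)
    kernel = np.ones(width) / np.sqrt(width)
    return np.convolve(w, kernel, mode="valid")


def _world_motion(profile: BehaviorProfile, n: int, fs: float, rng):
    """(n, 3) world-frame motion and an activity envelope in [0, 1]."""
    t = np.arange(n) / fs
    motion = np.zeros((n, 3))
    envelope = np.zeros(n)

    if profile.osc_freq_hz > 0 and max(profile.osc_amp) > 0:
        for ax in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            motion[:, ax] += profile.osc_amp[ax] * np.sin(
                2 * np.pi * profile.osc_freq_hz * t + phase)
        envelope = np.maximum(envelope, max(profile.osc_amp) > 0)

    if profile.burst_rate_hz > 0 and profile.burst_amp > 0:
        n_bursts = rng.poisson(profile.burst_rate_hz * n / fs)
        width_s = 0.3
        for _ in range(n_bursts):
            c = rng.uniform(0, n / fs)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pulse = profile.burst_amp * np.exp(-0.5 * ((t - c) / (width_s / 2)) ** 2)
            motion += pulse[:, None] * direction
            envelope = np.maximum(envelope, pulse / profile.burst_amp)

    if profile.peak_amp > 0:
        peak_n = max(1, int(round(profile.peak_len_s * fs)))
        env = np.zeros(n)
        env[:min(peak_n, n)] = 1.0
        env[max(0, n - peak_n):] = 1.0
        for ax in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            motion[:, ax] += env * profile.peak_amp * np.sin(
                2 * np.pi * profile.peak_freq_hz * t + phase)
        envelope = np.maximum(envelope, env)

    return motion, envelope


def generate_event(profile: BehaviorProfile, seed: int,
                   duration_s: float | None = None,
                   orientation: np.ndarray | None = None,
                   wobble_deg_s: float = 2.0,
                   cow_id: str = "cow01",
                   start: datetime | None = None,
                   behavior: str | None = None,
                   fs: float = SAMPLE_RATE_HZ) -> EventRecording:
    """One labeled synthetic event with every database channel populated.

    Body-frame specific force is R(q)^T (gravity + world motion) plus
    sensor noise; stored world-frame channels are exactly R(q) applied to
    the body-frame samples. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = max(profile.duration_min_s,
                         rng.normal(profile.duration_mean_s, profile.duration_sd_s))
    if duration_s < profile.duration_min_s:
        raise ValueError(f"duration {duration_s} below class minimum "
                         f"{profile.duration_min_s}")
    n = int(round(duration_s * fs))
    if orientation is None:
        orientation = make_orientation_trace(
            n, base=random_unit_quaternion(rng), wobble_deg_s=wobble_deg_s,
            seed=int(rng.integers(2 ** 31)), fs=fs)
    if len(orientation) < n:
        raise ValueError("orientation trace shorter than the event")
    orientation = orientation[:n]

    motion_w, envelope = _world_motion(profile, n, fs, rng)
    specific_force_w = motion_w + np.array([0.0, 0.0, GRAVITY])

    accel_body = np.empty((n, 3))
    mag_body = np.empty((n, 3))
    for i in range(n):
        R = quat_to_rotation(orientation[i])
        accel_body[i] = R.T @ specific_force_w[i]
        mag_body[i] = R.T @ MAGNETIC_FIELD
    accel_body += rng.normal(0, profile.noise_sd, size=(n, 3))
    mag_body += rng.normal(0, 0.5, size=(n, 3))

    accel_world = np.empty((n, 3))
    for i in range(n):
        accel_world[i] = quat_to_rotation(orientation[i]) @ accel_body[i]

    gyro_env = 0.2 + 0.8 * envelope if profile.peak_amp > 0 else np.ones(n)
    gyro = np.column_stack([
        profile.gyro_scale_dps * gyro_env * _smoothed_noise(rng, n)
        for _ in range(3)
    ])

    data = pd.DataFrame({
        "bno_ax_world": accel_world[:, 0], "bno_ay_world": accel_world[:, 1],
        "bno_az_world": accel_world[:, 2],
        "bno_ax_body": accel_body[:, 0], "bno_ay_body": accel_body[:, 1],
        "bno_az_body": accel_body[:, 2],
        "bno_gx": gyro[:, 0], "bno_gy": gyro[:, 1], "bno_gz": gyro[:, 2],
        "bno_mx": mag_body[:, 0], "bno_my": mag_body[:, 1],
        "bno_mz": mag_body[:, 2],
        "q1": orientation[:, 0], "q2": orientation[:, 1],
        "q3": orientation[:, 2], "q4": orientation[:, 3],
        "mpu_ax_body": accel_body[:, 0] + rng.normal(0, 0.05, n),
        "mpu_ay_body": accel_body[:, 1] + rng.normal(0, 0.05, n),
        "mpu_az_body": accel_body[:, 2] + rng.normal(0, 0.05, n),
        "mpu_gx": gyro[:, 0] + rng.normal(0, 0.1, n),
        "mpu_gy": gyro[:, 1] + rng.normal(0, 0.1, n),
        "mpu_gz": gyro[:, 2] + rng.normal(0, 0.1, n),
        "mpu_mx": mag_body[:, 0] + rng.normal(0, 0.5, n),
        "mpu_my": mag_body[:, 1] + rng.normal(0, 0.5, n),
        "mpu_mz": mag_body[:, 2] + rng.normal(0, 0.5, n),
    })
    behavior = behavior or profile.name
    return EventRecording(
        behavior=behavior, cow_id=cow_id,
        start=start or datetime(2024, 3, 1, 8, 0, 0),
        data=data, fs=fs,
    )


def encode_raw_counts(rec: EventRecording, spec: SensorSpec) -> pd.DataFrame:
    """Integer ADC counts for the body-frame acceleration and gyro channels.

    Nearest-integer inverse of the unit scaling; raises on clipping.
    """
    out = {}
    for c in ("bno_ax_body", "bno_ay_body", "bno_az_body"):
        out[c] = accel_to_raw(rec.data[c].to_numpy(), spec)
    for c in ("bno_gx", "bno_gy", "bno_gz"):
        out[c] = gyro_to_raw(rec.data[c].to_numpy(), spec)
    return pd.DataFrame(out)


def generate_events(counts: dict, seed: int, profiles: dict | None = None,
                    wobble_deg_s: float = 2.0) -> list[EventRecording]:
    """Labeled events for every behavior, deterministic under ``seed``."""
    profiles = profiles or DEFAULT_PROFILES
    root_ss = np.random.SeedSequence(seed)
    events = []
    base = datetime(2024, 3, 1, 6, 0, 0)
    minute = 0
    for behavior in BEHAVIORS:
        n_events = int(counts.get(behavior, 0))
        if n_events == 0:
            continue
        child_seeds = root_ss.spawn(1)[0].generate_state(n_events) % (2 ** 31)
        for k in range(n_events):
            events.append(generate_event(
                profiles[behavior], seed=int(child_seeds[k]),
                wobble_deg_s=wobble_deg_s,
                cow_id=f"cow{k % 8 + 1:02d}",
                start=base + timedelta(minutes=minute),
                behavior=behavior,
            ))
            minute += 5
    return events


def generate_database(root, counts: dict, seed: int,
                      profiles: dict | None = None,
                      wobble_deg_s: float = 2.0) -> Path:
    """Write a full directory-of-CSV database plus a manifest JSON."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    events = generate_events(counts, seed=seed, profiles=profiles,
                             wobble_deg_s=wobble_deg_s)
    manifest = {"seed": seed, "counts": {b: int(counts.get(b, 0)) for b in BEHAVIORS},
                "events": []}
    from .io_dataset import behavior_token
    for rec in events:
        path = write_event_csv(rec, root / behavior_token(rec.behavior))
        manifest["events"].append({
            "file": str(path.relative_to(root)),
            "behavior": rec.behavior,
            "duration_s": rec.duration_s,
        })
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root
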