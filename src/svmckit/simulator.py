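"""Synthetic sessions: ground-truth kinematics rendered as accelerometer streams.

The simulator exists to exercise the pipeline end to end without hardware or
patient data. It produces (a) ground-truth joint-angle traces for every
channel — the target joint tracking the star path with tunable lag and noise,
plus parameterized involuntary movements (mirror coupling of the contralateral
homologue, synergy coupling of other channels, trunk sway, tremor) — and (b)
the corresponding raw sensor streams: gravity rotated through the cumulative
segment-orientation chain, expressed in each sensor's frame, with white noise
and the hardware's irregular 29/58 Hz sampling (about 70%/30% of the time).

The sensor model is quasi-static (gravity only): movement accelerations in
this game are a few percent of g, so they are treated as part of the noise
term. Group-level impairment distributions are synthetic, tunable priors that
exist to exercise the scorer, not to model clinical populations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from ._errors import InvalidInputError
from .channels import (
    DEFAULT_CUTOFF_HZ,
    DEFAULT_RATE_HZ,
    JointChannel,
    SensorStream,
    derivative,
    lowpass,
    uniform_grid,
)
from .game import CalibrationResult, TargetPath, calibrate_arom, generate_target_path
from .scoring import ProcessedSession, SessionMeta, process_session
from .tables import ExtremityTable, load_channel_table

#: typical raw active ROM (degrees) per joint kind, used when none is supplied
DEFAULT_RAW_AROM_DEG = {
    "hip_flexion": 40.0,
    "hip_rotation": 35.0,
    "knee": 70.0,
    "ankle": 38.0,
    "shoulder_abd": 60.0,
    "elbow": 90.0,
    "forearm_prosup": 100.0,
    "wrist": 60.0,
    "fingers": 50.0,
}


@dataclass
class ImpairmentProfile:
    """Tunable impairment parameters injected into a simulated session."""

    tracking_noise_sd: float = 0.0  # percent of aROM, around the tracked path
    tracking_lag_s: float = 0.0
    mirror_gain: float = 0.0  # contralateral coupling of the target derivative
    synergy_gains: dict[str, float] = field(default_factory=dict)
    trunk_sway_amp: float = 0.0  # degrees
    trunk_sway_hz: float = 0.3
    tremor_amp: float = 0.0  # degrees, added to the target channel
    tremor_hz: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tracking_noise_sd", "trunk_sway_amp", "tremor_amp"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.trunk_sway_hz < 0 or self.tremor_hz < 0:
            raise InvalidInputError("frequencies must be >= 0")


@dataclass
class SamplingSpec:
    """Irregular-rate sampling: alternating 29/58 Hz segments.

    Segment durations are gamma-distributed (shape ``segment_shape``) with
    means in the ratio of ``time_fractions``, so the expected fraction of
    session time spent at each rate matches the hardware's 0.7/0.3 split.
    """

    rates: tuple[float, float] = (29.0, 58.0)
    time_fractions: tuple[float, float] = (0.7, 0.3)
    mean_cycle_s: float = 5.0
    segment_shape: float = 4.0


def sample_timestamps(
    rng: np.random.Generator, t_end: float, spec: SamplingSpec = SamplingSpec()
) -> np.ndarray:
    """Draw an irregular timestamp vector covering [0, t_end]."""
    means = (
        spec.time_fractions[0] * spec.mean_cycle_s,
        spec.time_fractions[1] * spec.mean_cycle_s,
    )
    state = 0 if rng.random() < spec.time_fractions[0] else 1
    ts = [0.0]
    t = 0.0
    while t < t_end:
        rate = spec.rates[state]
        dur = rng.gamma(spec.segment_shape, means[state] / spec.segment_shape)
        n = max(1, int(round(dur * rate)))
        seg = t + np.arange(1, n + 1) / rate
        ts.append(seg)
        t = float(seg[-1])
        state = 1 - state
    out = np.concatenate([np.atleast_1d(x) for x in ts])
    return out[out <= t_end + 1.0 / min(spec.rates)]


def realized_58hz_fraction(t: np.ndarray, split_hz: float = 40.0) -> float:
    """Fraction of record time sampled faster than ``split_hz`` (i.e. at 58 Hz)."""
    dt = np.diff(np.asarray(t, dtype=float))
    fast = dt < 1.0 / split_hz
    return float(np.sum(dt[fast]) / np.sum(dt))


# ---------------------------------------------------------------------------
# kinematics


def _delayed(p: np.ndarray, lag_s: float, rate_hz: float) -> np.ndarray:
    k = int(round(lag_s * rate_hz))
    if k <= 0:
        return p.copy()
    return np.concatenate([np.full(k, p[0]), p[:-k]])


def simulate_kinematics(
    path: TargetPath,
    calibration: CalibrationResult,
    table: ExtremityTable,
    target_joint: str,
    profile: ImpairmentProfile,
    seed: int,
    baselines: Optional[Mapping[str, float]] = None,
) -> dict[str, np.ndarray]:
    """Ground-truth angle traces for every channel on the path grid.

    The target angle is the inverse avatar mapping applied to the path,
    delayed by the tracking lag and perturbed by smoothed Gaussian tracking
    noise. The contralateral homologue's derivative is ``mirror_gain`` times
    the target derivative (realized by integrating, i.e. coupling the angle
    excursion); synergy channels likewise with their own gains; trunk channels
    sway sinusoidally. Everything else holds its baseline posture.
    """
    if not calibration.playable:
        raise InvalidInputError("cannot simulate against an unplayable calibration")
    rng = np.random.default_rng(seed)
    t = path.t_grid
    rate = path.rate_hz
    p_eff = _delayed(path.p_star, profile.tracking_lag_s, rate)
    if profile.tracking_noise_sd > 0:
        noise = rng.standard_normal(t.size)
        noise = lowpass(noise, min(2.0, 0.45 * rate), rate)
        sd = float(np.std(noise))
        if sd > 0:
            noise *= profile.tracking_noise_sd / sd
        p_eff = p_eff + noise
    p_eff = np.clip(p_eff, 0.0, 100.0)
    theta_t = calibration.arom_min + p_eff / 100.0 * calibration.span
    if profile.tremor_amp > 0:
        theta_t = theta_t + profile.tremor_amp * np.sin(2 * np.pi * profile.tremor_hz * t)

    baselines = dict(baselines or {})
    truth: dict[str, np.ndarray] = {
        c: np.full(t.size, float(baselines.get(c, 0.0))) for c in table.channels
    }
    truth[target_joint] = theta_t
    excursion = theta_t - theta_t[0]
    homologue = table.homologue(target_joint)
    if homologue is not None and profile.mirror_gain != 0.0:
        truth[homologue] = truth[homologue] + profile.mirror_gain * excursion
    for ch, gain in profile.synergy_gains.items():
        if ch == target_joint:
            continue
        table.require_channel(ch)
        truth[ch] = truth[ch] + gain * excursion
    if profile.trunk_sway_amp > 0:
        w = 2 * np.pi * profile.trunk_sway_hz * t
        truth["trunk_lateral"] = truth["trunk_lateral"] + profile.trunk_sway_amp * np.sin(w)
        truth["trunk_ventral"] = truth["trunk_ventral"] + profile.trunk_sway_amp * np.sin(
            w + np.pi / 2
        )
    return truth


def kinematics_to_accel(
    truth: Mapping[str, np.ndarray],
    t_truth: np.ndarray,
    table: ExtremityTable,
    seed: int,
    noise_sd_g: float = 0.005,
    sampling: SamplingSpec = SamplingSpec(),
    t_end: Optional[float] = None,
) -> dict[str, SensorStream]:
    """Render truth traces as raw sensor streams.

    Each sensor's orientation is the signed sum of the channel angles proximal
    to it along its chain, split into the sagittal ('xy') and frontal ('zy')
    planes; the reading is gravity expressed in that rotated frame plus white
    noise. All sensors share one irregular timestamp vector (the hardware
    transmits only when every sensor has a reading).
    """
    t_truth = np.asarray(t_truth, dtype=float)
    t_end = float(t_truth[-1]) if t_end is None else t_end
    rng = np.random.default_rng(seed)
    ts = sample_timestamps(rng, t_end, sampling)

    def chain_angle(sensor: str, plane: str) -> np.ndarray:
        total = np.zeros(ts.size)
        for ch in table.orientation_chain[sensor].get(plane, ()):
            sgn = table.channels[ch].sign
            total += sgn * np.interp(ts, t_truth, np.asarray(truth[ch], dtype=float))
        return np.radians(total)

    streams: dict[str, SensorStream] = {}
    for sensor in table.sensors:
        alpha = chain_angle(sensor, "xy")
        beta = chain_angle(sensor, "zy")
        a = np.column_stack(
            [
                -np.sin(alpha),
                -np.cos(alpha) * np.cos(beta),
                np.cos(alpha) * np.sin(beta),
            ]
        )
        a = a + rng.normal(0.0, noise_sd_g, a.shape)
        streams[sensor] = SensorStream(sensor_id=sensor, t=ts.copy(), a=a, placement=sensor)
    return streams


# ---------------------------------------------------------------------------
# sessions and cohorts


@dataclass
class SimSession:
    """A complete synthetic session: metadata, truth, raw streams."""

    meta: SessionMeta
    profile: ImpairmentProfile
    calibration: CalibrationResult
    path: TargetPath
    truth: dict[str, np.ndarray]
    streams: dict[str, SensorStream]
    seed: int


def _calibration_sweep(
    raw_span: float,
    rate_hz: float = DEFAULT_RATE_HZ,
    duration_s: float = 10.0,
    base_deg: float = 0.0,
) -> JointChannel:
    """A 10 s calibration recording sweeping the raw active range."""
    t = uniform_grid(0.0, duration_s, rate_hz)
    mid = base_deg + raw_span / 2.0
    angle = mid - (raw_span / 2.0) * np.cos(2 * np.pi * 0.25 * t)
    return JointChannel(name="calibration", t=t, angle=angle, rate_hz=rate_hz)


def simulate_session(
    target_joint: str,
    profile: ImpairmentProfile,
    seed: int,
    extremity: str = "LE",
    group: str = "NIA",
    age: float = 30.0,
    participant: str = "",
    raw_arom_deg: Optional[float] = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    duration_s: float = 30.0,
    noise_sd_g: float = 0.005,
    path: Optional[TargetPath] = None,
    sampling: SamplingSpec = SamplingSpec(),
) -> SimSession:
    """Simulate one full session (calibration, truth kinematics, raw streams)."""
    table = load_channel_table(extremity)
    table.require_channel(target_joint)
    rng = np.random.default_rng(seed)
    kind = table.joint_kind(target_joint)
    if raw_arom_deg is None:
        raw_arom_deg = DEFAULT_RAW_AROM_DEG[kind] * rng.uniform(0.9, 1.1)
    cal_trace = _calibration_sweep(raw_arom_deg, rate_hz)
    calibration = calibrate_arom(cal_trace, target_joint, table)
    if path is None:
        path = generate_target_path(duration_s, rate_hz=rate_hz)
    truth = simulate_kinematics(
        path, calibration, table, target_joint, profile, seed=int(rng.integers(2**31))
    )
    streams = kinematics_to_accel(
        truth,
        path.t_grid,
        table,
        seed=int(rng.integers(2**31)),
        noise_sd_g=noise_sd_g,
        sampling=sampling,
    )
    side = target_joint[-1] if target_joint.endswith(("_L", "_R")) else ""
    meta = SessionMeta(
        participant=participant,
        age=age,
        group=group,
        extremity=table.extremity,
        target_joint=target_joint,
        side=side,
    )
    return SimSession(
        meta=meta,
        profile=profile,
        calibration=calibration,
        path=path,
        truth=truth,
        streams=streams,
        seed=seed,
    )


def process_sim_session(sim: SimSession, **kwargs) -> ProcessedSession:
    """Run a simulated session through the real analysis pipeline."""
    table = load_channel_table(sim.meta.extremity)
    return process_session(
        sim.streams, table, sim.calibration, sim.path, meta=sim.meta, **kwargs
    )


def _same_side_channels(table: ExtremityTable, target_joint: str) -> list[str]:
    side = target_joint[-2:]
    return [
        c
        for c in table.channels
        if c.endswith(side) and c != target_joint and not c.startswith("trunk")
    ]


def draw_profile(
    group: str, age: float, rng: np.random.Generator, table: ExtremityTable, target_joint: str
) -> ImpairmentProfile:
    """Draw a per-participant impairment profile from group-level priors.

    Intact adults (NIA) get minimal impairment; intact children (NIC) get a
    mirror gain that decreases with age (mirror movements are physiological in
    younger children and fade by roughly age 10); patients (P) get elevated,
    heterogeneous gains on all components.
    """
    same_side = _same_side_channels(table, target_joint)
    if group == "NIA":
        synergy = {}
        if same_side:
            synergy = {str(rng.choice(same_side)): float(rng.uniform(0.0, 0.06))}
        return ImpairmentProfile(
            tracking_noise_sd=float(rng.uniform(1.5, 3.5)),
            tracking_lag_s=float(rng.uniform(0.08, 0.18)),
            mirror_gain=float(rng.uniform(0.0, 0.04)),
            synergy_gains=synergy,
            trunk_sway_amp=float(rng.uniform(0.3, 1.0)),
            trunk_sway_hz=float(rng.uniform(0.2, 0.5)),
        )
    if group == "NIC":
        # mirror movements are physiological and prominent in young children,
        # fading to near the adult level by roughly age 10-12
        age_factor = float(np.clip((12.0 - age) / 6.0, 0.0, 1.0))
        synergy = {}
        if same_side:
            synergy = {str(rng.choice(same_side)): float(rng.uniform(0.0, 0.1))}
        return ImpairmentProfile(
            tracking_noise_sd=float(rng.uniform(2.0, 5.0)),
            tracking_lag_s=float(rng.uniform(0.1, 0.25)),
            mirror_gain=float(rng.uniform(0.15, 0.6)) * age_factor,
            synergy_gains=synergy,
            trunk_sway_amp=float(rng.uniform(0.5, 1.5)),
            trunk_sway_hz=float(rng.uniform(0.2, 0.6)),
        )
    if group == "P":
        picks = rng.choice(same_side, min(2, len(same_side)), replace=False) if same_side else []
        synergy = {str(c): float(rng.uniform(0.05, 0.5)) for c in picks}
        return ImpairmentProfile(
            tracking_noise_sd=float(rng.uniform(3.0, 8.0)),
            tracking_lag_s=float(rng.uniform(0.1, 0.35)),
            mirror_gain=float(rng.uniform(0.15, 0.9)),
            synergy_gains=synergy,
            trunk_sway_amp=float(rng.uniform(1.0, 5.0)),
            trunk_sway_hz=float(rng.uniform(0.3, 0.8)),
        )
    raise InvalidInputError(f"unknown group {group!r}")


def simulate_cohort(
    n: int,
    group: str,
    seed: int,
    extremity: str = "LE",
    target_joint: str = "ankle_L",
    age_range: Optional[tuple[float, float]] = None,
    path: Optional[TargetPath] = None,
    **session_kwargs,
) -> list[SimSession]:
    """Simulate ``n`` participants of one group, reproducible from ``seed``."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    table = load_channel_table(extremity)
    rng = np.random.default_rng(seed)
    if age_range is None:
        age_range = (20.0, 45.0) if group == "NIA" else (6.0, 17.0)
    if path is None:
        path = generate_target_path(rate_hz=session_kwargs.get("rate_hz", DEFAULT_RATE_HZ))
    sessions = []
    for i in range(n):
        age = float(rng.uniform(*age_range))
        profile = draw_profile(group, age, rng, table, target_joint)
        sessions.append(
            simulate_session(
                target_joint,
                profile,
                seed=int(rng.integers(2**31)),
                extremity=extremity,
                group=group,
                age=age,
                participant=f"{group}_{i + 1:03d}",
                path=path,
                **session_kwargs,
            )
        )
    return sessions


def composite_impairment(sim: SimSession) -> float:
    """Ground-truth impairment summary of a simulated session.

    Total involuntary motion relative to target motion: the sum over
    non-target channels of the RMS truth angle derivative, divided by the RMS
    derivative of the target channel. Mirror gain g contributes g, each
    synergy gain likewise, and trunk sway its normalized sway velocity.
    """
    rate = sim.path.rate_hz
    d_target = derivative(sim.truth[sim.meta.target_joint], rate)
    rms_target = float(np.sqrt(np.mean(d_target**2)))
    total = 0.0
    for ch, trace in sim.truth.items():
        if ch == sim.meta.target_joint:
            continue
        d = derivative(trace, rate)
        total += float(np.sqrt(np.mean(d**2)))
    return total / rms_target
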