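"""Accelerometer streams to joint-angle channels.

The sensors deliver tri-axial acceleration in units of g at an irregular rate
(native 29 Hz most of the time, 58 Hz otherwise). Movement is slow enough that
the reading is dominated by gravity, so a sensor's orientation within a chosen
measurement plane is the two-argument arctangent of two axis components
("inclination"). A joint channel is the pointwise difference between the
inclinations of the distal and proximal sensor of a pair — the proximal sensor
acts as reference, so rigid compensatory movement of everything proximal to
the joint cancels exactly and cannot steer the game.

Processing order per channel: resample both sensors onto a common uniform
grid, compute inclinations (flagging ill-conditioned samples where gravity is
nearly orthogonal to the plane), unwrap and gap-fill, subtract proximal from
distal, low-pass filter (zero-phase Butterworth). Angle derivatives use
central differences, so a constant — even if wrong — posture contributes zero:
players unable to hold a starting position are not penalized.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from scipy import signal as _sig

from ._errors import InvalidInputError
from .tables import ExtremityTable

DEFAULT_RATE_HZ = 29.0
DEFAULT_CUTOFF_HZ = 3.0
DEFAULT_FLOOR_G = 0.05
DEFAULT_MAX_GAP_S = 0.5

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class AxisConvention:
    """Inclination convention: angle = atan2(num_sign*a[num], den_sign*a[den]).

    The default sagittal convention ('xy') reads 0 degrees when the sensor
    y-axis is anti-parallel to the measured acceleration of a hanging limb
    (reading (0, -1, 0) g) and +90 degrees at (-1, 0, 0) g; range (-180, 180].
    """

    num: str
    den: str
    num_sign: float = -1.0
    den_sign: float = -1.0

    def components(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(a, dtype=float)
        return (
            self.num_sign * a[..., _AXIS[self.num]],
            self.den_sign * a[..., _AXIS[self.den]],
        )


#: Measurement planes used by the shipped channel tables.
PLANES: dict[str, AxisConvention] = {
    "xy": AxisConvention("x", "y", -1.0, -1.0),
    "zy": AxisConvention("z", "y", 1.0, -1.0),
}


@dataclass
class SensorStream:
    """One sensor's acceleration record. ``t`` seconds, ``a`` shape (n, 3) in g."""

    sensor_id: str
    t: np.ndarray
    a: np.ndarray
    placement: str = ""
    role: str = "distal"  # "proximal-reference" | "distal"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.t.ndim != 1 or self.a.shape != (self.t.size, 3):
            raise InvalidInputError(
                f"stream {self.sensor_id}: t must be 1-d and a of shape (n, 3)"
            )
        if not np.all(np.isfinite(self.t)) or np.any(self.t < 0):
            raise InvalidInputError(f"stream {self.sensor_id}: timestamps must be finite and >= 0")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class JointChannel:
    """A named joint/trunk angle trace on a uniform time grid (degrees)."""

    name: str
    t: np.ndarray
    angle: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.t.shape != self.angle.shape or self.t.ndim != 1:
            raise InvalidInputError(f"channel {self.name}: t/angle shape mismatch")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.rate_hz)) > 1e-9:
                raise InvalidInputError(f"channel {self.name}: grid not uniform at {self.rate_hz} Hz")
        if not np.all(np.isfinite(self.angle)):
            raise InvalidInputError(f"channel {self.name}: non-finite angles")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class ChannelSet:
    """Output of :func:`compute_joint_channels`."""

    channels: dict[str, JointChannel]
    missing: list[str]
    t: np.ndarray
    rate_hz: float


# ---------------------------------------------------------------------------
# elementary operations


def uniform_grid(t_start: float, t_end: float, rate_hz: float) -> np.ndarray:
    """Arithmetic grid at ``rate_hz`` spanning [t_start, t_end] (no extrapolation)."""
    if rate_hz <= 0:
        raise InvalidInputError("rate_hz must be positive")
    n = int(np.floor((t_end - t_start) * rate_hz + 1e-9)) + 1
    return t_start + np.arange(n) / rate_hz


def resample_uniform(stream: SensorStream, rate_hz: float) -> SensorStream:
    """Linearly interpolate a stream onto a uniform grid spanning its record."""
    if stream.n < 2:
        raise InvalidInputError(f"stream {stream.sensor_id}: need >= 2 samples to resample")
    if np.any(np.diff(stream.t) <= 0):
        raise InvalidInputError(f"stream {stream.sensor_id}: timestamps not strictly increasing")
    tg = uniform_grid(stream.t[0], stream.t[-1], rate_hz)
    a = np.column_stack([np.interp(tg, stream.t, stream.a[:, k]) for k in range(3)])
    return replace(stream, t=tg, a=a)


def inclination_angle(
    a: np.ndarray, convention: Union[str, AxisConvention] = "xy"
) -> Union[float, np.ndarray]:
    """Signed gravity-direction angle (degrees) within the convention's plane.

    Vectorized over leading axes; raises for an exactly-zero in-plane vector on
    scalar input (ill-conditioned *samples* in a series are handled by
    :func:`sensor_inclination` instead).
    """
    conv = PLANES[convention] if isinstance(convention, str) else convention
    num, den = conv.components(a)
    if np.ndim(num) == 0 and float(np.hypot(num, den)) == 0.0:
        raise InvalidInputError("in-plane acceleration is zero; angle undefined")
    return np.degrees(np.arctan2(num, den))


def sensor_inclination(
    a: np.ndarray,
    convention: Union[str, AxisConvention] = "xy",
    floor_g: float = DEFAULT_FLOOR_G,
) -> np.ndarray:
    """Per-sample inclination series with ill-conditioned samples set to NaN.

    A sample is ill-conditioned when the in-plane gravity component falls
    below ``floor_g`` (the plane is nearly orthogonal to gravity and the
    arctangent is dominated by noise).
    """
    conv = PLANES[convention] if isinstance(convention, str) else convention
    num, den = conv.components(a)
    ang = np.degrees(np.arctan2(num, den))
    ang = np.where(np.hypot(num, den) < floor_g, np.nan, ang)
    return ang


def fill_flagged(
    angles: np.ndarray, rate_hz: float, max_gap_s: float = DEFAULT_MAX_GAP_S
) -> tuple[np.ndarray, bool]:
    """Unwrap a flagged (NaN-bearing) angle series and bridge short gaps.

    Gaps up to ``max_gap_s`` (including leading/trailing runs) are filled by
    linear interpolation / nearest-edge extension on the unwrapped series.
    Returns ``(filled, usable)``; ``usable`` is False when any gap is too long
    or fewer than two valid samples exist — the channel is then marked missing.
    """
    x = np.asarray(angles, dtype=float).copy()
    valid = np.isfinite(x)
    if valid.sum() < 2:
        return x, False
    # longest NaN run
    if not valid.all():
        idx = np.flatnonzero(valid)
        # interior gaps
        run_max = int(np.max(np.diff(idx))) - 1 if idx.size > 1 else 0
        run_max = max(run_max, int(idx[0]), int(x.size - 1 - idx[-1]))
        if run_max / rate_hz > max_gap_s:
            return x, False
    x[valid] = np.unwrap(x[valid], period=360.0)
    if not valid.all():
        pos = np.arange(x.size)
        x[~valid] = np.interp(pos[~valid], pos[valid], x[valid])
    return x, True


def pair_angle(proximal: np.ndarray, distal: np.ndarray) -> np.ndarray:
    """Joint angle as pointwise ``distal - proximal`` inclination (degrees).

    Any rotation common to both sensors cancels exactly, which is what stops
    proximal compensation from steering the avatar.
    """
    p = np.asarray(proximal, dtype=float)
    d = np.asarray(distal, dtype=float)
    if p.shape != d.shape:
        raise InvalidInputError("pair_angle: proximal/distal traces on mismatched grids")
    return d - p


def lowpass(
    x: np.ndarray, cutoff_hz: float, rate_hz: float, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a uniformly sampled trace."""
    if not 0 < cutoff_hz < rate_hz / 2:
        raise InvalidInputError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rate_hz / 2} Hz)"
        )
    x = np.asarray(x, dtype=float)
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return _sig.sosfiltfilt(sos, x)


def lowpass_filter(
    channel: JointChannel, cutoff_hz: float = DEFAULT_CUTOFF_HZ, order: int = 2
) -> JointChannel:
    """Zero-phase low-pass of a channel; DC traces pass unchanged."""
    return replace(channel, angle=lowpass(channel.angle, cutoff_hz, channel.rate_hz, order))


def derivative(
    channel: Union[JointChannel, np.ndarray], rate_hz: Optional[float] = None
) -> np.ndarray:
    """Angle derivative in deg/s: central differences interior, one-sided ends.

    A constant trace maps to exactly zero, so a held (even if wrong) posture
    contributes nothing to the involuntary-movement error.
    """
    if isinstance(channel, JointChannel):
        x, rate = channel.angle, channel.rate_hz
    else:
        if rate_hz is None:
            raise InvalidInputError("derivative: rate_hz required for raw arrays")
        x, rate = np.asarray(channel, dtype=float), rate_hz
    if x.size < 3:
        raise InvalidInputError("derivative: need at least 3 samples")
    return np.gradient(x, 1.0 / rate)


# ---------------------------------------------------------------------------
# whole-session channel computation


def _as_stream_map(
    streams: Union[Mapping[str, SensorStream], Iterable[SensorStream]],
) -> dict[str, SensorStream]:
    if isinstance(streams, Mapping):
        return dict(streams)
    return {s.sensor_id: s for s in streams}


def compute_joint_channels(
    streams: Union[Mapping[str, SensorStream], Iterable[SensorStream]],
    table: ExtremityTable,
    t_grid: Optional[np.ndarray] = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    floor_g: float = DEFAULT_FLOOR_G,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> ChannelSet:
    """Compute every channel in the extremity's table from raw sensor streams.

    All channels are delivered on one common uniform grid (``t_grid`` if given,
    otherwise the overlap of the available streams at ``rate_hz``). A channel
    whose sensors are absent, do not cover the grid, or are ill-conditioned for
    longer than ``max_gap_s`` is reported in ``missing`` rather than failing
    the whole session.
    """
    smap = _as_stream_map(streams)
    if t_grid is None:
        present = [s for s in smap.values() if s.n >= 2]
        if not present:
            raise InvalidInputError("no usable sensor streams")
        t0 = max(float(s.t[0]) for s in present)
        t1 = min(float(s.t[-1]) for s in present)
        if t1 <= t0:
            raise InvalidInputError("sensor streams do not overlap in time")
        t_grid = uniform_grid(t0, t1, rate_hz)
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        rate_hz = 1.0 / float(np.mean(np.diff(t_grid)))

    tol = 1e-6
    series_cache: dict[tuple[str, str], Optional[np.ndarray]] = {}

    def sensor_series(sensor: str, plane: str) -> Optional[np.ndarray]:
        key = (sensor, plane)
        if key not in series_cache:
            out: Optional[np.ndarray] = None
            s = smap.get(sensor)
            if (
                s is not None
                and s.n >= 2
                and s.t[0] <= t_grid[0] + tol
                and s.t[-1] >= t_grid[-1] - tol
                and np.all(np.diff(s.t) > 0)
            ):
                a = np.column_stack(
                    [np.interp(t_grid, s.t, s.a[:, k]) for k in range(3)]
                )
                ang = sensor_inclination(a, plane, floor_g)
                filled, usable = fill_flagged(ang, rate_hz, max_gap_s)
                out = filled if usable else None
            series_cache[key] = out
        return series_cache[key]

    channels: dict[str, JointChannel] = {}
    missing: list[str] = []
    for name, cdef in table.channels.items():
        dist = sensor_series(cdef.distal, cdef.plane)
        if cdef.proximal is None:
            prox: Optional[np.ndarray] = np.zeros_like(t_grid)
        else:
            prox = sensor_series(cdef.proximal, cdef.plane)
        if dist is None or prox is None:
            missing.append(name)
            continue
        raw = cdef.sign * pair_angle(prox, dist)
        ang = lowpass(raw, cutoff_hz, rate_hz)
        channels[name] = JointChannel(name=name, t=t_grid, angle=ang, rate_hz=rate_hz)
    return ChannelSet(channels=channels, missing=missing, t=t_grid, rate_hz=rate_hz)
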