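"""Game mechanics: aROM calibration, target path, avatar mapping, analysis window.

The game is calibrated to each participant's *active* range of motion (aROM)
so the score reflects selective control rather than strength. The measured
span is capped at a per-joint maximum (hip 45, knee 90, ankle 90; shoulder 70,
elbow 110, forearm 135, wrist 135 degrees), then 5 degrees are pruned off each
end; a joint is playable only if at least ~20 degrees remain. The avatar
position is the target-joint angle expressed in percent of the calibrated
range, and the target path challenges the player within the central 90% band
([5, 95]%) for 30 s, of which the last 5 s keep the player engaged but are not
analyzed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._errors import InvalidInputError, UnplayableJointError
from .channels import DEFAULT_RATE_HZ, JointChannel, uniform_grid
from .tables import ExtremityTable, load_channel_table, load_default_waypoints

DEFAULT_DURATION_S = 30.0
DEFAULT_DISCARD_TAIL_S = 5.0
DEFAULT_PRUNE_DEG = 5.0
DEFAULT_MIN_PLAYABLE_DEG = 20.0
PATH_BAND = (5.0, 95.0)  # centered 90% of the calibrated range


@dataclass
class CalibrationResult:
    """Calibrated active ROM for one target joint."""

    joint: str
    extremity: str
    raw_min: float
    raw_max: float
    arom_min: float
    arom_max: float
    capped: bool
    playable: bool
    reason: Optional[str] = None

    @property
    def span(self) -> float:
        return self.arom_max - self.arom_min

    def to_dict(self) -> dict:
        return {
            "joint": self.joint,
            "extremity": self.extremity,
            "raw_min": self.raw_min,
            "raw_max": self.raw_max,
            "arom_min": self.arom_min,
            "arom_max": self.arom_max,
            "capped": self.capped,
            "playable": self.playable,
            "reason": self.reason,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(**d)


@dataclass
class TargetPath:
    """The predefined star path in percent of calibrated aROM."""

    t_grid: np.ndarray
    p_star: np.ndarray
    star_times: np.ndarray

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.p_star = np.asarray(self.p_star, dtype=float)
        self.star_times = np.asarray(self.star_times, dtype=float)

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.t_grid)))

    @property
    def duration(self) -> float:
        return float(self.t_grid[-1] - self.t_grid[0])


@dataclass
class AvatarTrace:
    """Avatar position in percent of calibrated aROM, clipped to [0, 100]."""

    t_grid: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.p = np.asarray(self.p, dtype=float)


def calibrate_arom(
    calibration_channel: JointChannel,
    joint: str,
    extremity: Union[str, ExtremityTable] = "LE",
    cap_deg: Union[float, None, str] = "auto",
    prune_deg: float = DEFAULT_PRUNE_DEG,
    min_playable_deg: float = DEFAULT_MIN_PLAYABLE_DEG,
    min_duration_s: float = 5.0,
) -> CalibrationResult:
    """Establish the playable range from a calibration recording.

    The raw extrema are capped at the joint's maximum span (symmetrically
    about the measured midpoint), then ``prune_deg`` is removed from each end.
    ``playable`` requires the remaining span to reach ``min_playable_deg``.
    When the capped span cannot survive pruning the capped bounds are kept and
    the joint is flagged unplayable with a reason.
    """
    table = extremity if isinstance(extremity, ExtremityTable) else load_channel_table(extremity)
    if calibration_channel.duration + 1e-9 < min_duration_s:
        raise InvalidInputError(
            f"calibration trace covers {calibration_channel.duration:.2f} s; "
            f"need >= {min_duration_s} s"
        )
    raw_min = float(np.min(calibration_channel.angle))
    raw_max = float(np.max(calibration_channel.angle))
    cap = table.cap_for(joint) if cap_deg == "auto" else cap_deg

    lo, hi = raw_min, raw_max
    capped = False
    if cap is not None and (hi - lo) > cap:
        mid = 0.5 * (lo + hi)
        lo, hi = mid - cap / 2.0, mid + cap / 2.0
        capped = True

    if (hi - lo) <= 2.0 * prune_deg:
        return CalibrationResult(
            joint=joint,
            extremity=table.extremity,
            raw_min=raw_min,
            raw_max=raw_max,
            arom_min=lo,
            arom_max=hi,
            capped=capped,
            playable=False,
            reason=f"range {hi - lo:.1f} deg <= 2 x {prune_deg:.0f} deg pruning",
        )

    lo, hi = lo + prune_deg, hi - prune_deg
    playable = (hi - lo) >= min_playable_deg
    return CalibrationResult(
        joint=joint,
        extremity=table.extremity,
        raw_min=raw_min,
        raw_max=raw_max,
        arom_min=lo,
        arom_max=hi,
        capped=capped,
        playable=playable,
        reason=None if playable else (
            f"calibrated span {hi - lo:.1f} deg below minimum playable "
            f"{min_playable_deg:.0f} deg"
        ),
    )


def generate_target_path(
    duration_s: float = DEFAULT_DURATION_S,
    waypoints: Optional[Sequence[tuple[float, float]]] = None,
    seed: Optional[int] = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    n_waypoints: int = 12,
) -> TargetPath:
    """Build the 30 s target path through waypoints (time_s, percent).

    With neither waypoints nor seed the built-in default shape is used; with a
    seed, waypoints are drawn deterministically within the [5, 95] band and
    forced to span it (reach <= 10 and >= 90). Interpolation is shape-preserving
    cubic (PCHIP), so the path never overshoots the waypoint band.
    """
    lo, hi = PATH_BAND
    if waypoints is None:
        if seed is None:
            waypoints = [(t, p) for t, p in load_default_waypoints() if t <= duration_s]
        else:
            rng = np.random.default_rng(seed)
            times = np.linspace(0.0, duration_s, max(4, n_waypoints))
            vals = rng.uniform(15.0, 85.0, times.size)
            i_lo, i_hi = rng.choice(np.arange(1, times.size - 1), 2, replace=False)
            vals[i_lo] = rng.uniform(lo, 10.0)
            vals[i_hi] = rng.uniform(90.0, hi)
            waypoints = list(zip(times, vals))
    pts = sorted((float(t), float(p)) for t, p in waypoints)
    for _, p in pts:
        if not (lo <= p <= hi):
            raise InvalidInputError(f"waypoint value {p} outside band [{lo}, {hi}]")
    t_grid = uniform_grid(0.0, duration_s, rate_hz)
    if len(pts) == 1:
        p_star = np.full_like(t_grid, pts[0][1])
        star_times = np.array([pts[0][0]])
    else:
        tw = np.array([t for t, _ in pts])
        pw = np.array([p for _, p in pts])
        interp = PchipInterpolator(tw, pw, extrapolate=False)
        p_star = interp(np.clip(t_grid, tw[0], tw[-1]))
        star_times = tw
    return TargetPath(t_grid=t_grid, p_star=p_star, star_times=star_times)


def avatar_position(
    target_channel: JointChannel, calibration: CalibrationResult
) -> AvatarTrace:
    """Map the target-joint angle to avatar percent of calibrated aROM."""
    if not calibration.playable:
        raise UnplayableJointError(
            f"target joint {calibration.joint!r} failed calibration: {calibration.reason}"
        )
    p = 100.0 * (target_channel.angle - calibration.arom_min) / calibration.span
    return AvatarTrace(t_grid=target_channel.t, p=np.clip(p, 0.0, 100.0))


def analysis_window(
    trace: Union[JointChannel, AvatarTrace, TargetPath],
    duration_s: float = DEFAULT_DURATION_S,
    discard_tail_s: float = DEFAULT_DISCARD_TAIL_S,
):
    """Keep the first ``duration_s - discard_tail_s`` seconds of a trace.

    The final seconds of play keep participants engaged until the end of the
    game but are excluded from the analysis.
    """
    t = trace.t_grid if hasattr(trace, "t_grid") else trace.t
    if t[-1] - t[0] + 1e-9 < duration_s:
        raise InvalidInputError(
            f"trace covers {t[-1] - t[0]:.2f} s; analysis window needs {duration_s} s"
        )
    keep = (t - t[0]) <= duration_s - discard_tail_s + 1e-9
    if isinstance(trace, TargetPath):
        t_end = t[keep][-1]
        return TargetPath(
            t_grid=t[keep],
            p_star=trace.p_star[keep],
            star_times=trace.star_times[trace.star_times <= t_end + 1e-9],
        )
    if isinstance(trace, AvatarTrace):
        return AvatarTrace(t_grid=t[keep], p=trace.p[keep])
    return replace(trace, t=t[keep], angle=trace.angle[keep])
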