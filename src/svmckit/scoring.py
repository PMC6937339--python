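"""Normative standardized-error scoring.

Two interval-scaled outcomes summarize a session:

* **accuracy** — mean over the analysis window of
  ``|p(t) - p*(t)| / sigma_path(t)``, the avatar's distance from the target
  path in units of the adult reference SD around that same path. Dividing by
  a per-timepoint SD makes deviations comparable across path segments of
  different difficulty.
* **involuntary movements** — for every monitored non-target channel, the
  mean of ``|d_c(t) - mu_c(t)| / sigma_c(t)`` where ``d_c`` is the channel's
  angle derivative and ``mu_c``/``sigma_c`` are the adult mean and SD
  derivative traces. Standardizing against the adult *mean* (not zero) avoids
  penalizing physiological co-movement. Channel errors are averaged within
  joint units (e.g. both hip channels of one side) and the unit means are
  averaged with equal weight into one score.

The adult reference is fitted statsmodels-style: ``NormativeReference.fit``
estimates the per-timepoint traces from processed adult sessions and
``NormativeReference.score`` returns a :class:`SessionScores` results object.
Age normalization re-expresses a raw score as a z-value against peers (intact
children within +/- 1 year of the participant's integer age; intact adults
against the whole adult group); positive z = worse than peer average.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from ._errors import InvalidInputError, UnplayableJointError
from .channels import ChannelSet, DEFAULT_CUTOFF_HZ, DEFAULT_RATE_HZ, SensorStream, compute_joint_channels, derivative
from .game import (
    AvatarTrace,
    CalibrationResult,
    DEFAULT_DISCARD_TAIL_S,
    DEFAULT_DURATION_S,
    TargetPath,
    analysis_window,
    avatar_position,
)
from .tables import ExtremityTable, GROUPS, load_channel_table

DEFAULT_SD_FLOOR = 0.5  # native units: percent for the path, deg/s for derivatives
MIN_PEER_GROUP = 3


@dataclass
class SessionMeta:
    participant: str = ""
    age: float = float("nan")
    group: str = "NIA"
    extremity: str = "LE"
    target_joint: str = ""
    side: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class ProcessedSession:
    """A session reduced to the analysis-window traces scoring needs."""

    meta: SessionMeta
    path: TargetPath
    avatar: AvatarTrace
    derivs: dict[str, np.ndarray]
    missing: list[str] = field(default_factory=list)

    @property
    def t(self) -> np.ndarray:
        return self.path.t_grid


def process_session(
    streams: Union[Mapping[str, SensorStream], Iterable[SensorStream]],
    table: ExtremityTable,
    calibration: CalibrationResult,
    path: TargetPath,
    meta: Optional[SessionMeta] = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    duration_s: float = DEFAULT_DURATION_S,
    discard_tail_s: float = DEFAULT_DISCARD_TAIL_S,
) -> ProcessedSession:
    """Raw streams -> windowed avatar trace + per-channel derivatives.

    Channels are computed on the path's grid so that path, avatar and every
    derivative trace share one analysis-window grid.
    """
    meta = meta or SessionMeta(extremity=table.extremity)
    target = meta.target_joint or calibration.joint
    cs: ChannelSet = compute_joint_channels(
        streams, table, t_grid=path.t_grid, cutoff_hz=cutoff_hz
    )
    if target not in cs.channels:
        raise UnplayableJointError(f"target channel {target!r} missing from session")
    if not calibration.playable:
        raise UnplayableJointError(
            f"target joint {target!r} failed calibration: {calibration.reason}"
        )
    avatar = avatar_position(cs.channels[target], calibration)
    path_w = analysis_window(path, duration_s, discard_tail_s)
    avatar_w = analysis_window(avatar, duration_s, discard_tail_s)
    derivs: dict[str, np.ndarray] = {}
    for name in table.monitored_channels(target):
        if name in cs.channels:
            ch_w = analysis_window(cs.channels[name], duration_s, discard_tail_s)
            derivs[name] = derivative(ch_w)
    missing = [c for c in table.monitored_channels(target) if c not in derivs]
    new_meta = SessionMeta(
        participant=meta.participant,
        age=meta.age,
        group=meta.group,
        extremity=table.extremity,
        target_joint=target,
        side=meta.side,
    )
    return ProcessedSession(
        meta=new_meta, path=path_w, avatar=avatar_w, derivs=derivs, missing=missing
    )


# ---------------------------------------------------------------------------
# elementary score operations


def _check_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if np.shape(a) != np.shape(b):
        raise InvalidInputError(f"{what}: traces on mismatched grids")


def accuracy_score(
    avatar: AvatarTrace,
    path: TargetPath,
    ref: "NormativeReference",
    method: str = "pointwise",
) -> float:
    """Standardized target-path error, averaged over the analysis window.

    ``method='pointwise'`` (default) standardizes each timepoint before
    averaging; ``'aggregate'`` averages the absolute deviation and the SD
    separately first (sensitivity-analysis variant).
    """
    _check_grid(avatar.p, path.p_star, "accuracy_score")
    _check_grid(avatar.p, ref.sigma_path, "accuracy_score (reference)")
    dev = np.abs(avatar.p - path.p_star)
    if method == "pointwise":
        return float(np.mean(dev / ref.sigma_path))
    if method == "aggregate":
        return float(np.mean(dev) / np.mean(ref.sigma_path))
    raise InvalidInputError(f"unknown accuracy method {method!r}")


def involuntary_channel_error(
    channel_deriv: np.ndarray, mu_c: np.ndarray, sigma_c: np.ndarray
) -> float:
    """Mean standardized distance of a channel's derivative from the adult mean."""
    d = np.asarray(channel_deriv, dtype=float)
    _check_grid(d, mu_c, "involuntary_channel_error")
    _check_grid(d, sigma_c, "involuntary_channel_error")
    return float(np.mean(np.abs(d - mu_c) / sigma_c))


def handle_missing_channels(
    per_channel: Mapping[str, Optional[float]], strategy: str = "drop"
) -> dict[str, float]:
    """Apply the missing-channel policy to a per-channel error map.

    ``drop`` (default) removes missing (None) channels so unit averages are
    taken over available members; ``fail`` raises if anything is missing.
    Externally imputed values can simply be supplied in ``per_channel`` —
    that is the imputation hook.
    """
    missing = [c for c, v in per_channel.items() if v is None]
    if strategy == "fail":
        if missing:
            raise InvalidInputError(f"missing channels under strategy='fail': {missing}")
        return {c: float(v) for c, v in per_channel.items()}  # type: ignore[arg-type]
    if strategy == "drop":
        kept = {c: float(v) for c, v in per_channel.items() if v is not None}
        if not kept:
            raise InvalidInputError("all channels missing; cannot score involuntary movements")
        return kept
    raise InvalidInputError(f"unknown missing-channel strategy {strategy!r}")


def aggregate_involuntary(
    per_channel: Mapping[str, float],
    target_joint: str,
    table: ExtremityTable,
) -> tuple[float, dict[str, float]]:
    """Two-level average: channels -> joint units -> one involuntary score.

    The target channel never enters (it is scored by the accuracy metric);
    units whose channels are all unavailable are excluded.
    """
    units = table.aggregation_units(target_joint)
    per_unit: dict[str, float] = {}
    for unit, members in units.items():
        vals = [per_channel[c] for c in members if c in per_channel]
        if vals:
            per_unit[unit] = float(np.mean(vals))
    if not per_unit:
        raise InvalidInputError("no joint units available after missing-channel handling")
    return float(np.mean(list(per_unit.values()))), per_unit


# ---------------------------------------------------------------------------
# the fitted adult reference


@dataclass
class NormativeReference:
    """Per-timepoint adult reference statistics for one target joint.

    ``sigma_path`` is the SD across adults of the avatar's deviation from the
    target path; ``mu``/``sigma`` hold each monitored channel's adult mean and
    SD derivative trace. All SDs are floored at ``sd_floor`` so degenerate
    (near-deterministic) references cannot blow up a score.
    """

    target_joint: str
    extremity: str
    t: np.ndarray
    sigma_path: np.ndarray
    mu: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]
    n_adults: int
    sd_floor: float = DEFAULT_SD_FLOOR
    rate_hz: float = DEFAULT_RATE_HZ

    def __post_init__(self) -> None:
        if self.n_adults < 2:
            raise InvalidInputError("reference needs at least 2 adult sessions")
        if self.sd_floor <= 0:
            raise InvalidInputError("sd_floor must be positive")

    @classmethod
    def fit(
        cls,
        sessions: Sequence[ProcessedSession],
        sd_floor: float = DEFAULT_SD_FLOOR,
        table: Optional[ExtremityTable] = None,
    ) -> "NormativeReference":
        """Estimate the reference traces from processed adult sessions.

        All sessions must share the target joint and the identical path grid.
        Channel statistics are fitted for channels present in every session.
        """
        if len(sessions) < 2:
            raise InvalidInputError("need >= 2 adult sessions to fit a reference")
        first = sessions[0]
        target = first.meta.target_joint
        t = first.t
        for s in sessions[1:]:
            if s.meta.target_joint != target:
                raise InvalidInputError("sessions mix target joints")
            if s.t.shape != t.shape or not np.allclose(s.t, t, atol=1e-9):
                raise InvalidInputError("sessions scored on different paths/grids")
            if not np.allclose(s.path.p_star, first.path.p_star, atol=1e-9):
                raise InvalidInputError("sessions scored on different paths/grids")
        dev = np.stack([s.avatar.p - s.path.p_star for s in sessions])
        sigma_path = np.maximum(np.std(dev, axis=0, ddof=1), sd_floor)
        common = set(sessions[0].derivs)
        for s in sessions[1:]:
            common &= set(s.derivs)
        mu: dict[str, np.ndarray] = {}
        sigma: dict[str, np.ndarray] = {}
        for c in sorted(common):
            mat = np.stack([s.derivs[c] for s in sessions])
            mu[c] = np.mean(mat, axis=0)
            sigma[c] = np.maximum(np.std(mat, axis=0, ddof=1), sd_floor)
        rate = 1.0 / float(np.mean(np.diff(t)))
        return cls(
            target_joint=target,
            extremity=first.meta.extremity,
            t=t.copy(),
            sigma_path=sigma_path,
            mu=mu,
            sigma=sigma,
            n_adults=len(sessions),
            sd_floor=sd_floor,
            rate_hz=rate,
        )

    def score(
        self,
        session: ProcessedSession,
        missing_strategy: str = "drop",
        table: Optional[ExtremityTable] = None,
        accuracy_method: str = "pointwise",
    ) -> "SessionScores":
        """Score one processed session against this reference."""
        if session.meta.target_joint != self.target_joint:
            raise InvalidInputError(
                f"session target {session.meta.target_joint!r} != reference "
                f"target {self.target_joint!r}"
            )
        table = table or load_channel_table(self.extremity)
        acc = accuracy_score(session.avatar, session.path, self, accuracy_method)
        raw: dict[str, Optional[float]] = {}
        for c in table.monitored_channels(self.target_joint):
            if c in session.derivs and c in self.mu:
                raw[c] = involuntary_channel_error(
                    session.derivs[c], self.mu[c], self.sigma[c]
                )
            else:
                raw[c] = None
        per_channel = handle_missing_channels(raw, missing_strategy)
        invol, per_unit = aggregate_involuntary(per_channel, self.target_joint, table)
        return SessionScores(
            meta=session.meta,
            accuracy=acc,
            involuntary=invol,
            per_channel=per_channel,
            per_joint_unit=per_unit,
            missing_channels=[c for c, v in raw.items() if v is None],
        )


# ---------------------------------------------------------------------------
# results object and age normalization


@dataclass
class ZScoreResult:
    z: Optional[float]
    n_peers: int
    reason: Optional[str] = None


def age_normalize(
    score: float,
    age: float,
    group: str,
    cohort: Iterable[tuple[float, str, float]],
    min_peers: int = MIN_PEER_GROUP,
) -> ZScoreResult:
    """z-transform a raw score against an age-matched peer group.

    For children and patients the peers are the neurologically intact
    children whose integer age lies within +/- 1 year of the participant's
    integer age; intact adults are normalized against the whole adult group.
    Positive z = worse (more error) than the peer average.
    """
    if group not in GROUPS:
        raise InvalidInputError(f"group must be one of {GROUPS}, got {group!r}")
    records = [(float(a), g, float(s)) for a, g, s in cohort]
    if group == "NIA":
        peers = [s for a, g, s in records if g == "NIA"]
    else:
        lo, hi = int(age) - 1, int(age) + 1
        peers = [s for a, g, s in records if g == "NIC" and lo <= int(a) <= hi]
    n = len(peers)
    if n < min_peers:
        return ZScoreResult(None, n, f"peer group has {n} members (< {min_peers})")
    mean = float(np.mean(peers))
    sd = float(np.std(peers, ddof=1))
    if sd == 0.0:
        return ZScoreResult(None, n, "peer group has zero SD")
    return ZScoreResult((score - mean) / sd, n)


@dataclass
class SessionScores:
    """The two standardized-error outcomes with their per-channel breakdown."""

    meta: SessionMeta
    accuracy: float
    involuntary: float
    per_channel: dict[str, float]
    per_joint_unit: dict[str, float]
    missing_channels: list[str] = field(default_factory=list)
    z_accuracy: Optional[float] = None
    z_involuntary: Optional[float] = None
    z_reason: Optional[str] = None

    def add_z_scores(
        self,
        cohort_accuracy: Iterable[tuple[float, str, float]],
        cohort_involuntary: Iterable[tuple[float, str, float]],
    ) -> "SessionScores":
        za = age_normalize(self.accuracy, self.meta.age, self.meta.group, cohort_accuracy)
        zi = age_normalize(
            self.involuntary, self.meta.age, self.meta.group, cohort_involuntary
        )
        self.z_accuracy = za.z
        self.z_involuntary = zi.z
        self.z_reason = za.reason or zi.reason
        return self

    def summary(self) -> str:
        m = self.meta
        lines = [
            "Selective voluntary motor control — session scores",
            "=" * 52,
            f"participant: {m.participant or '-'}   group: {m.group}   age: {m.age:g}",
            f"extremity: {m.extremity}   target joint: {m.target_joint}   side: {m.side or '-'}",
            "-" * 52,
            f"accuracy (adult-SD units)     {self.accuracy:10.3f}",
            f"involuntary movements         {self.involuntary:10.3f}",
        ]
        if self.z_accuracy is not None:
            lines.append(f"z accuracy (age-normalized)   {self.z_accuracy:10.3f}")
        if self.z_involuntary is not None:
            lines.append(f"z involuntary                 {self.z_involuntary:10.3f}")
        lines.append("-" * 52)
        lines.append("joint units:")
        for unit, val in sorted(self.per_joint_unit.items()):
            lines.append(f"  {unit:<22s}{val:10.3f}")
        lines.append("channels:")
        for ch, val in sorted(self.per_channel.items()):
            lines.append(f"  {ch:<22s}{val:10.3f}")
        if self.missing_channels:
            lines.append(f"missing channels: {', '.join(self.missing_channels)}")
        return "\n".join(lines)


def score_cohort(
    sessions: Sequence[ProcessedSession],
    ref: NormativeReference,
    missing_strategy: str = "drop",
    normalize_age: bool = True,
) -> list[SessionScores]:
    """Score many sessions and (optionally) attach age-normalized z-scores."""
    scores = [ref.score(s, missing_strategy) for s in sessions]
    if normalize_age:
        acc = [(s.meta.age, s.meta.group, s.accuracy) for s in scores]
        inv = [(s.meta.age, s.meta.group, s.involuntary) for s in scores]
        for s in scores:
            s.add_z_scores(acc, inv)
    return scores
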