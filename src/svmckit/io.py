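"""File formats: sensor-stream CSV, JSON artifacts, tidy score tables.

All numeric output is written at full double precision; units are stated in
headers/keys (seconds, g, degrees, percent). Writers round-trip losslessly
through their readers.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._errors import InvalidInputError
from .channels import SensorStream
from .game import CalibrationResult, TargetPath
from .scoring import NormativeReference, SessionMeta, SessionScores
from .tables import GROUPS

REFERENCE_FORMAT_VERSION = 1
STREAM_COLUMNS = ["t", "ax", "ay", "az", "sensor_id"]  # seconds, g-units


# ---------------------------------------------------------------------------
# sensor streams (long-format CSV)


def write_streams_csv(streams, path: Union[str, Path]) -> None:
    frames = []
    items = streams.values() if hasattr(streams, "values") else streams
    for s in items:
        frames.append(
            pd.DataFrame(
                {
                    "t": s.t,
                    "ax": s.a[:, 0],
                    "ay": s.a[:, 1],
                    "az": s.a[:, 2],
                    "sensor_id": s.sensor_id,
                }
            )
        )
    # %.17g guarantees bit-exact float64 round-trips through the CSV
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_streams_csv(path: Union[str, Path]) -> dict[str, SensorStream]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"stream CSV {path} lacks columns {missing}")
    out: dict[str, SensorStream] = {}
    for sid, grp in df.groupby("sensor_id", sort=False):
        out[str(sid)] = SensorStream(
            sensor_id=str(sid),
            t=grp["t"].to_numpy(float),
            a=grp[["ax", "ay", "az"]].to_numpy(float),
        )
    return out


# ---------------------------------------------------------------------------
# JSON artifacts


def _dump(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=1))


def _load(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def write_calibration_json(cal: CalibrationResult, path) -> None:
    _dump(cal.to_dict(), path)


def read_calibration_json(path) -> CalibrationResult:
    return CalibrationResult.from_dict(_load(path))


def write_path_json(p: TargetPath, path) -> None:
    _dump(
        {
            "t_grid_s": p.t_grid.tolist(),
            "p_star_percent": p.p_star.tolist(),
            "star_times_s": p.star_times.tolist(),
        },
        path,
    )


def read_path_json(path) -> TargetPath:
    d = _load(path)
    return TargetPath(
        t_grid=np.array(d["t_grid_s"]),
        p_star=np.array(d["p_star_percent"]),
        star_times=np.array(d["star_times_s"]),
    )


def write_truth_json(truth: dict[str, np.ndarray], t: np.ndarray, path) -> None:
    _dump(
        {"t_s": np.asarray(t).tolist(), "angles_deg": {c: np.asarray(v).tolist() for c, v in truth.items()}},
        path,
    )


def read_truth_json(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    d = _load(path)
    return np.array(d["t_s"]), {c: np.array(v) for c, v in d["angles_deg"].items()}


def write_reference_json(ref: NormativeReference, path) -> None:
    _dump(
        {
            "format_version": REFERENCE_FORMAT_VERSION,
            "target_joint": ref.target_joint,
            "extremity": ref.extremity,
            "rate_hz": ref.rate_hz,
            "n_adults": ref.n_adults,
            "sd_floor": ref.sd_floor,
            "t_s": ref.t.tolist(),
            "sigma_path_percent": ref.sigma_path.tolist(),
            "channels_deg_per_s": {
                c: {"mu": ref.mu[c].tolist(), "sigma": ref.sigma[c].tolist()}
                for c in ref.mu
            },
        },
        path,
    )


def read_reference_json(path) -> NormativeReference:
    d = _load(path)
    if d.get("format_version") != REFERENCE_FORMAT_VERSION:
        raise InvalidInputError(
            f"unsupported reference format version {d.get('format_version')!r}"
        )
    chans = d["channels_deg_per_s"]
    return NormativeReference(
        target_joint=d["target_joint"],
        extremity=d["extremity"],
        t=np.array(d["t_s"]),
        sigma_path=np.array(d["sigma_path_percent"]),
        mu={c: np.array(v["mu"]) for c, v in chans.items()},
        sigma={c: np.array(v["sigma"]) for c, v in chans.items()},
        n_adults=int(d["n_adults"]),
        sd_floor=float(d["sd_floor"]),
        rate_hz=float(d["rate_hz"]),
    )


# ---------------------------------------------------------------------------
# session manifest


@dataclass
class SessionManifest:
    """Metadata + file layout for one recorded or simulated session."""

    participant: str
    age: float
    group: str
    extremity: str
    target_joint: str
    tested_side: str = ""
    dominant_side: str = ""
    streams_file: str = "streams.csv"
    calibration_file: str = "calibration.json"
    path_file: str = "path.json"
    placement_map_file: Optional[str] = None
    therapist_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.therapist_score is not None and self.therapist_score not in (0, 1, 2, 3):
            raise InvalidInputError("therapist_score must be 0..3 when present")

    def meta(self) -> SessionMeta:
        return SessionMeta(
            participant=self.participant,
            age=self.age,
            group=self.group,
            extremity=self.extremity,
            target_joint=self.target_joint,
            side=self.tested_side,
        )


def write_manifest_json(m: SessionManifest, path) -> None:
    _dump(asdict(m), path)


def read_manifest_json(path) -> SessionManifest:
    return SessionManifest(**_load(path))


def save_session_dir(sim, out_dir: Union[str, Path]) -> Path:
    """Write a simulated session as a self-contained session directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_streams_csv(sim.streams, out / "streams.csv")
    write_calibration_json(sim.calibration, out / "calibration.json")
    write_path_json(sim.path, out / "path.json")
    write_truth_json(sim.truth, sim.path.t_grid, out / "truth.json")
    _dump(
        {
            "tracking_noise_sd": sim.profile.tracking_noise_sd,
            "tracking_lag_s": sim.profile.tracking_lag_s,
            "mirror_gain": sim.profile.mirror_gain,
            "synergy_gains": sim.profile.synergy_gains,
            "trunk_sway_amp": sim.profile.trunk_sway_amp,
            "trunk_sway_hz": sim.profile.trunk_sway_hz,
            "tremor_amp": sim.profile.tremor_amp,
            "tremor_hz": sim.profile.tremor_hz,
            "seed": sim.seed,
        },
        out / "profile.json",
    )
    m = SessionManifest(
        participant=sim.meta.participant,
        age=sim.meta.age,
        group=sim.meta.group,
        extremity=sim.meta.extremity,
        target_joint=sim.meta.target_joint,
        tested_side=sim.meta.side,
    )
    write_manifest_json(m, out / "manifest.json")
    return out


def load_session_dir(session_dir: Union[str, Path]) -> dict:
    """Read a session directory back: manifest, streams, calibration, path."""
    d = Path(session_dir)
    manifest = read_manifest_json(d / "manifest.json")
    return {
        "manifest": manifest,
        "streams": read_streams_csv(d / manifest.streams_file),
        "calibration": read_calibration_json(d / manifest.calibration_file),
        "path": read_path_json(d / manifest.path_file),
    }


# ---------------------------------------------------------------------------
# tidy scores table


def scores_to_frame(scores: Sequence[SessionScores]) -> pd.DataFrame:
    """One row per (participant, side, target joint); per-unit columns included."""
    rows = []
    for s in scores:
        row = {
            "participant": s.meta.participant,
            "age": s.meta.age,
            "group": s.meta.group,
            "extremity": s.meta.extremity,
            "target_joint": s.meta.target_joint,
            "side": s.meta.side,
            "accuracy": s.accuracy,
            "involuntary": s.involuntary,
            "z_accuracy": s.z_accuracy,
            "z_involuntary": s.z_involuntary,
            "missing_channels": ";".join(s.missing_channels),
        }
        for unit, v in s.per_joint_unit.items():
            row[f"unit_{unit}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores_csv(scores: Sequence[SessionScores], path) -> None:
    scores_to_frame(scores).to_csv(path, index=False)
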