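"""Channel tables: the editable map from sensors to joint channels.

Each extremity ships a JSON table declaring, per channel, the proximal/distal
sensor pair, the measurement plane (which accelerometer axes the inclination
arctangent reads), and the steering sign; plus the joint-unit grouping used to
aggregate involuntary-movement errors and the per-joint range-of-motion caps
applied during calibration. Keeping this in one data file isolates the
deployment-specific conventions (exact per-joint formulas, up/down mappings)
from the processing code.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from ._errors import InvalidInputError, UnknownLabelError

#: trunk channels are monitored on both extremities but are never steering targets
TRUNK_CHANNELS = ("trunk_lateral", "trunk_ventral")

GROUPS = ("NIA", "NIC", "P")  # intact adults / intact children / pediatric patients


@dataclass(frozen=True)
class ChannelDef:
    """One joint channel: distal-minus-proximal inclination in a fixed plane."""

    name: str
    proximal: Optional[str]  # None -> gravity reference (trunk channels)
    distal: str
    plane: str  # "xy" or "zy"
    sign: float = 1.0


@dataclass(frozen=True)
class ExtremityTable:
    extremity: str
    sensors: tuple[str, ...]
    channels: dict[str, ChannelDef]
    units: dict[str, tuple[str, ...]]
    targets: tuple[str, ...]
    caps_deg: dict[str, Optional[float]]
    orientation_chain: dict[str, dict[str, tuple[str, ...]]]

    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def require_channel(self, name: str) -> ChannelDef:
        try:
            return self.channels[name]
        except KeyError:
            raise UnknownLabelError(
                f"unknown channel {name!r} for extremity {self.extremity}"
            ) from None

    def joint_kind(self, channel: str) -> str:
        """Strip the side suffix: 'hip_flexion_L' -> 'hip_flexion'."""
        self.require_channel(channel)
        if channel.endswith(("_L", "_R")):
            return channel[:-2]
        return channel

    def cap_for(self, channel: str) -> Optional[float]:
        """Maximum allowed aROM span for a target channel (None = uncapped)."""
        return self.caps_deg.get(self.joint_kind(channel))

    def homologue(self, channel: str) -> Optional[str]:
        """Contralateral counterpart of a sided channel, else None."""
        self.require_channel(channel)
        if channel.endswith("_L"):
            other = channel[:-2] + "_R"
        elif channel.endswith("_R"):
            other = channel[:-2] + "_L"
        else:
            return None
        return other if other in self.channels else None

    def aggregation_units(self, target_joint: str) -> dict[str, tuple[str, ...]]:
        """Joint units monitored for a given target: the target channel is
        removed and units left empty by its removal are dropped."""
        if target_joint not in self.targets:
            raise UnknownLabelError(
                f"{target_joint!r} is not a playable target for {self.extremity}"
            )
        out: dict[str, tuple[str, ...]] = {}
        for unit, members in self.units.items():
            kept = tuple(c for c in members if c != target_joint)
            if kept:
                out[unit] = kept
        return out

    def monitored_channels(self, target_joint: str) -> tuple[str, ...]:
        """All channels entering the involuntary score for this target."""
        seen: list[str] = []
        for members in self.aggregation_units(target_joint).values():
            seen.extend(members)
        return tuple(seen)


def _parse_table(raw: dict) -> ExtremityTable:
    channels = {
        name: ChannelDef(
            name=name,
            proximal=spec["proximal"],
            distal=spec["distal"],
            plane=spec["plane"],
            sign=float(spec.get("sign", 1.0)),
        )
        for name, spec in raw["channels"].items()
    }
    sensors = tuple(raw["sensors"])
    for cdef in channels.values():
        for s in (cdef.proximal, cdef.distal):
            if s is not None and s not in sensors:
                raise InvalidInputError(
                    f"channel {cdef.name} references unknown sensor {s!r}"
                )
        if cdef.plane not in ("xy", "zy"):
            raise InvalidInputError(f"channel {cdef.name}: unknown plane {cdef.plane!r}")
    units = {u: tuple(m) for u, m in raw["units"].items()}
    for unit, members in units.items():
        for c in members:
            if c not in channels:
                raise InvalidInputError(f"unit {unit} references unknown channel {c!r}")
    chain = {
        s: {plane: tuple(chs) for plane, chs in planes.items()}
        for s, planes in raw["orientation_chain"].items()
    }
    return ExtremityTable(
        extremity=raw["extremity"],
        sensors=sensors,
        channels=channels,
        units=units,
        targets=tuple(raw["targets"]),
        caps_deg={k: (None if v is None else float(v)) for k, v in raw["caps_deg"].items()},
        orientation_chain=chain,
    )


def load_channel_table_json(path) -> ExtremityTable:
    with open(path) as fh:
        return _parse_table(json.load(fh))


def load_channel_table(extremity: str) -> ExtremityTable:
    """Load the built-in channel table for 'LE' or 'UE'."""
    ext = extremity.upper()
    if ext not in ("LE", "UE"):
        raise InvalidInputError(f"extremity must be 'LE' or 'UE', got {extremity!r}")
    ref = resources.files("svmckit.data") / f"channels_{ext.lower()}.json"
    return _parse_table(json.loads(ref.read_text()))


def load_default_waypoints() -> list[tuple[float, float]]:
    ref = resources.files("svmckit.data") / "waypoints_default.json"
    raw = json.loads(ref.read_text())
    return [(float(t), float(p)) for t, p in raw["waypoints"]]
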