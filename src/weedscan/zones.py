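"""Mapping detections to lateral actuation zones and driving relays.

The camera's on-ground field of view (1 m wide by default) is split into
``n_zones`` equal strips (four 25 cm zones by default). Each strip is tied
to one output channel — in the field a GPIO pin driving a relay and
solenoid — which is switched on for a fixed duration whenever a weed is
detected inside the strip. This module keeps the timing logic pure and
testable: activations are scheduled as (start, duration) intervals and an
abstract backend turns them into on/off transitions. The shipped
``MockRelayBackend`` records a timestamped transition log; a hardware
backend only needs to honour the same two-method contract.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

from .pipeline import Detection

__all__ = [
    "ZoneConfig",
    "ZoneActivation",
    "assign_zone",
    "schedule_activations",
    "drive_backend",
    "MockRelayBackend",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZoneConfig:
    n_zones: int = 4
    frame_width: int = 416
    fov_width: float = 1.0  # metres on the ground
    pin_map: tuple[int, ...] = (13, 15, 16, 18)  # zone index -> channel id
    activation_duration: float = 200.0  # milliseconds

    def __post_init__(self) -> None:
        if self.n_zones < 1:
            raise ValueError("need at least one zone")
        if self.frame_width < self.n_zones:
            raise ValueError("frame narrower than the zone count")
        if len(self.pin_map) != self.n_zones or len(set(self.pin_map)) != self.n_zones:
            raise ValueError("pin_map must assign one distinct channel per zone")
        if self.activation_duration <= 0:
            raise ValueError("activation duration must be positive")

    @property
    def zone_width_ground(self) -> float:
        """Ground width of one zone in metres (fov_width / n_zones)."""
        return self.fov_width / self.n_zones


@dataclass
class ZoneActivation:
    zone: int
    channel: int
    start_time: float  # ms
    duration: float  # ms
    source_frame: int = 0

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


def assign_zone(centroid_x: float, config: ZoneConfig) -> int:
    """Map a detection centre's x pixel to its actuation zone.

    Half-open equal-width bins cover [0, frame_width) exactly; the floor is
    clamped so the right frame edge still lands in the last zone.
    """
    if not 0 <= centroid_x < config.frame_width:
        raise ValueError(
            f"centroid x {centroid_x} outside frame [0, {config.frame_width})"
        )
    zone = int(centroid_x * config.n_zones // config.frame_width)
    return min(zone, config.n_zones - 1)


def schedule_activations(
    detections: Sequence[Detection],
    now: float,
    config: ZoneConfig,
    pending: list[ZoneActivation] | None = None,
) -> list[ZoneActivation]:
    """Update the pending-activation list for one frame's detections.

    Each distinct zone hit this frame gets a single activation (per-zone
    dedup). A zone that is already active is retriggered: its end time is
    extended to ``now + duration`` rather than queueing a duplicate, which
    keeps a nozzle open continuously over contiguous weeds.
    """
    pending = list(pending) if pending is not None else []
    hit_zones: dict[int, int] = {}
    for det in detections:
        zone = det.zone if det.zone is not None else assign_zone(det.centroid[0], config)
        hit_zones.setdefault(zone, det.frame_index)
    for zone, frame_index in sorted(hit_zones.items()):
        active = next(
            (a for a in pending if a.zone == zone and a.end_time > now), None
        )
        if active is not None:
            active.duration = now + config.activation_duration - active.start_time
            active.source_frame = frame_index
        else:
            pending.append(
                ZoneActivation(
                    zone=zone,
                    channel=config.pin_map[zone],
                    start_time=now,
                    duration=config.activation_duration,
                    source_frame=frame_index,
                )
            )
    return pending


class ActuationBackend(Protocol):
    def set_channel(self, channel: int, on: bool, t_ms: float) -> None: ...


@dataclass
class MockRelayBackend:
    """Records relay transitions instead of switching hardware."""

    transitions: list[tuple[int, str, float]] = field(default_factory=list)

    def set_channel(self, channel: int, on: bool, t_ms: float) -> None:
        self.transitions.append((channel, "on" if on else "off", t_ms))

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["channel", "state", "t_ms"])
            writer.writerows(self.transitions)


def drive_backend(
    activations: Sequence[ZoneActivation], backend: ActuationBackend
) -> list[tuple[int, str, float]]:
    """Emit on/off transitions for a set of activations.

    Overlapping or retrigger-extended intervals on the same channel are
    merged first so each spray burst produces exactly one on and one off
    transition (no relay glitching). A failing backend is logged and
    reported, never allowed to crash the detection loop.
    """
    merged: dict[int, list[list[float]]] = {}
    for act in sorted(activations, key=lambda a: (a.channel, a.start_time)):
        spans = merged.setdefault(act.channel, [])
        if spans and act.start_time <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], act.end_time)
        else:
            spans.append([act.start_time, act.end_time])
    events: list[tuple[int, bool, float]] = []
    for channel, spans in merged.items():
        for start, end in spans:
            events.append((channel, True, start))
            events.append((channel, False, end))
    events.sort(key=lambda e: (e[2], e[0], not e[1]))
    emitted: list[tuple[int, str, float]] = []
    for channel, on, t in events:
        try:
            backend.set_channel(channel, on, t)
        except Exception:  # noqa: BLE001 - actuation must not kill detection
            log.exception("actuation backend failed on channel %s", channel)
            continue
        emitted.append((channel, "on" if on else "off", t))
    return emitted
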